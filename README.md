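# symbiospot

Tools for two measurements on chemosymbiotic bivalve gills whose
sulfur-oxidizing symbionts occur as two 16S rRNA phylotypes differing at a
single base (alleles A and G):

1. **Spatial phylotype mapping.** Spatially barcoded paired reads (read 1 =
   25-base coordinate barcode + 10-base molecular barcode, read 2 = 75-base
   16S fragments) are demultiplexed to chip spots and classified at
   single-nucleotide resolution: a read is assigned to phylotype A or G only
   if it contains the full 47-nt diagnostic window of that reference with
   zero mismatches (or, in alignment mode, passes the NH:i:1 / MAPQ 255 /
   CIGAR 47M filter and carries the diagnostic-position allele). Spot counts
   are aggregated into 20 × 20-spot bins (≈ one host cell); a bin is valid
   from 180 classified reads, and a dominant phylotype is called when its
   read fraction strictly exceeds 95% — equivalently when the count ratio
   A/G (or G/A) exceeds 19. Heterogeneity summaries report the 5%-interval
   frequency histogram, the share of extreme bins, single-phylotype
   fractions and neighbour discordance.

2. **Radiotracer carbon-fixation kinetics.** From ¹⁴C-bicarbonate
   incubations, the DIC turnover rate constant is

   k = −ln(1 − DPM_POC / DPM_DIC) / t   [day⁻¹]

   and the assimilation rate is k × [DIC] × 10⁶ × V × n (nmol C·day⁻¹),
   with [DIC] in mmol·L⁻¹, V the incubation volume in litres (0.015 live
   clam, 0.010 gill vial) and n the per-clam normalisation (1 or 4).
   Seawater incubations are normalised per 100 ml, a clam's fixation can be
   expressed as an equivalent seawater volume, and the temperature response
   of k is fitted with quadratic/cubic least squares, the thermal optimum
   located from the cubic's derivative in closed form.

A synthetic-data module generates spatially barcoded read sets over planted
two-phylotype fields and simulated scintillation measurements with Poisson
counting noise, so the whole pipeline is testable without any sequencing
data.

## Worked example

```sh
python examples/temperature_response.py
```

```
quadratic R² = 0.9305
cubic     R² = 1.0000 (interpolates the four means)
thermal optimum of the cubic: 14.75 °C
mean k as % of maximum: {'5°C': '42%', '12°C': '100%', '20°C': '94%', '28°C': '69%'}
```

With four mean (temperature, k) points the cubic fit interpolates exactly;
its derivative — a quadratic solved in closed form — puts the optimum
temperature for carbon fixation at 14.75 °C, and the warmest assay
temperature retains 69% of the maximal rate constant.

```sh
python examples/spatial_phylotyping.py
```

```
reads: 40317  classified A: 3283  G: 3958  unclassified: 33076  dropped: 0
valid bins (>=180 reads): 25
single-phylotype bins (dominance sense): 80.0%
extreme-frequency share (0-5% + 95-100%): 80.0%
neighbour discordance: 0.000
sample-level phylotype-G frequency: 0.547
```

Most reads are unclassified because a random 75-nt fragment usually misses
the 47-nt diagnostic window — as in real capture; on a two-domain planted
field, 80% of the valid bins are dominated by a single phylotype and the
discordance between neighbouring dominant calls is confined to domain
boundaries. `examples/simulate_sample.py` and
`examples/carbon_fixation_rates.py` demonstrate the generator and the rate
equations; the same stages are scriptable via the `symbiospot
simulate|phylotype|rates|report` CLI.

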