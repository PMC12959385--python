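"""End-to-end runs: simulate, phylotype, rates — with manifests.

Each run writes a JSON manifest recording inputs, parameters, seed,
package version, emitted files and stage counters, so any output can be
reproduced from its manifest alone.  Identical configuration and seed
give byte-identical tabular outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

import symbiospot
from symbiospot import phylotyping, rates, synthetic

logger = logging.getLogger("symbiospot")

__all__ = ["run_simulate", "run_phylotype", "run_rates", "run_report"]


def _write_manifest(outdir: Path, name: str, payload: dict) -> Path:
    payload = {"symbiospot_version": symbiospot.__version__, **payload}
    path = outdir / name
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path


def run_simulate(
    outdir,
    seed: int = 0,
    grid_width: int = 100,
    grid_height: int = 100,
    field_model: str = "domain-mosaic",
    n_domains: int = 2,
    mixing_beta: float = 1000.0,
    mean_reads_per_spot: float = 10.0,
    error_rate: float = 0.001,
    incubation_true_k: float = 7.4e-4,
    incubation_replicates: int = 6,
) -> dict:
    """Generate a full synthetic input set into ``outdir``.

    Emits references (FASTA), paired reads (FASTQ), the barcode mask and
    truth table (TSV), simulated incubations (TSV) and a manifest listing
    every file.  Reruns with the same seed reproduce identical content.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = synthetic.make_reference_pair(seed)
    field_cfg = synthetic.FieldConfig(
        grid_width=grid_width, grid_height=grid_height, field_model=field_model,
        n_domains=n_domains, mixing_beta=mixing_beta, seed=seed + 1,
    )
    truth = synthetic.simulate_field(field_cfg)
    read_cfg = synthetic.ReadSimConfig(
        mean_reads_per_spot=mean_reads_per_spot, error_rate=error_rate, seed=seed + 2
    )
    reads = synthetic.simulate_reads(truth, refs, read_cfg)
    inc_cfg = synthetic.IncubationSimConfig(
        true_k=incubation_true_k, counting_noise="poisson", seed=seed + 3
    )
    incubations = synthetic.simulate_incubation(inc_cfg, incubation_replicates)

    files = {
        "references": outdir / "references.fasta",
        "read1": outdir / "reads_R1.fastq",
        "read2": outdir / "reads_R2.fastq",
        "mask": outdir / "mask.tsv",
        "truth": outdir / "truth.tsv",
        "incubations": outdir / "incubations.tsv",
    }
    refs.to_fasta(files["references"])
    reads.write_fastq(files["read1"], files["read2"])
    reads.write_mask(files["mask"])
    truth.to_tsv(files["truth"])
    synthetic.write_incubations(incubations, files["incubations"])

    manifest = {
        "stage": "simulate",
        "seed": seed,
        "parameters": {
            "grid_width": grid_width, "grid_height": grid_height,
            "field_model": field_model, "n_domains": n_domains,
            "mixing_beta": mixing_beta,
            "mean_reads_per_spot": mean_reads_per_spot,
            "error_rate": error_rate,
            "incubation_true_k": incubation_true_k,
            "incubation_replicates": incubation_replicates,
        },
        "counters": {"n_spots": len(truth), "n_read_pairs": len(reads)},
        "files": {k: str(v) for k, v in files.items()},
    }
    _write_manifest(outdir, "manifest_simulate.json", manifest)
    logger.info("simulated %d read pairs over %d spots", len(reads), len(truth))
    return manifest


def run_phylotype(
    r1_path,
    r2_path,
    mask_path,
    refs_path,
    outdir,
    sam_path=None,
    bin_size: int = 20,
    min_reads: int = 180,
    dominance: float = 0.95,
    dedup_mid: bool = False,
) -> dict:
    """Demultiplex, classify, bin, call and summarise one sample.

    Sequence mode (default) classifies read 2 by exact 47-nt window
    matching; alignment mode (``sam_path``) instead ingests pre-aligned
    records through the unique/MAPQ/CIGAR filter, joining them to spots
    via read names.  Stage counters (reads in, demux-dropped, A, G,
    unclassified, valid bins) are logged and persisted in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = phylotyping.load_mask(mask_path)
    refs = synthetic.load_references(refs_path)

    counters = {"reads_in": 0, "demux_dropped": 0, "A": 0, "G": 0, "unclassified": 0}
    classified: list[phylotyping.ClassifiedRead] = []

    if sam_path is None:
        for rec1, rec2 in zip(SeqIO.parse(str(r1_path), "fastq"),
                              SeqIO.parse(str(r2_path), "fastq")):
            counters["reads_in"] += 1
            hit = phylotyping.demux(str(rec1.seq), mask)
            if hit is None:
                counters["demux_dropped"] += 1
                continue
            spot, mid = hit
            call = phylotyping.classify_read(str(rec2.seq), refs)
            counters[call if call in ("A", "G") else "unclassified"] += 1
            classified.append(phylotyping.ClassifiedRead(spot=spot, mid=mid, call=call))
    else:
        import pysam

        spot_by_name: dict[str, tuple[tuple[int, int], str]] = {}
        for rec1 in SeqIO.parse(str(r1_path), "fastq"):
            counters["reads_in"] += 1
            hit = phylotyping.demux(str(rec1.seq), mask)
            if hit is None:
                counters["demux_dropped"] += 1
                continue
            spot_by_name[rec1.id] = hit
        filt = phylotyping.AlignmentFilter()
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
            for aln in sam:
                hit = spot_by_name.get(aln.query_name)
                if hit is None:
                    continue
                spot, mid = hit
                call = phylotyping.classify_alignment(
                    aln, filt, refs.diagnostic_pos - 1
                )
                counters[call if call in ("A", "G") else "unclassified"] += 1
                classified.append(
                    phylotyping.ClassifiedRead(spot=spot, mid=mid, call=call)
                )

    spots = phylotyping.accumulate(classified, dedup_mid=dedup_mid)
    bins = phylotyping.call_bins(
        phylotyping.bin_aggregate(spots, bin_size=bin_size, min_reads=min_reads),
        dominance=dominance,
    )
    counters["valid_bins"] = int(bins["valid"].sum()) if len(bins) else 0

    files = {"spots": outdir / "spots.tsv", "bins": outdir / "bins.tsv",
             "summary": outdir / "summary.json"}
    spots.to_tsv(files["spots"])
    bins.to_csv(files["bins"], sep="\t", index=False)

    summary_payload: dict = {"counters": counters}
    if counters["valid_bins"] > 0:
        summary = phylotyping.summarize(bins)
        summary_payload["heterogeneity"] = summary.to_dict()
        n_a, n_g = int(bins["n_A"].sum()), int(bins["n_G"].sum())
        if n_a + n_g > 0:
            summary_payload["sample_frequency_G"] = phylotyping.sample_frequency(
                n_a, n_g
            ).frac_g
    files["summary"].write_text(json.dumps(summary_payload, indent=2) + "\n")

    manifest = {
        "stage": "phylotype",
        "parameters": {
            "bin_size": bin_size, "min_reads": min_reads,
            "dominance": dominance, "dedup_mid": dedup_mid,
            "mode": "alignment" if sam_path else "sequence",
        },
        "inputs": {"r1": str(r1_path), "r2": str(r2_path),
                   "mask": str(mask_path), "refs": str(refs_path),
                   "sam": str(sam_path) if sam_path else None},
        "counters": counters,
        "files": {k: str(v) for k, v in files.items()},
    }
    _write_manifest(outdir, "manifest_phylotype.json", manifest)
    logger.info("phylotype counters: %s", counters)
    return manifest


def run_rates(
    incubations_path,
    outdir,
    subtract_control: bool = False,
    fit_degree: Optional[int] = 3,
) -> dict:
    """Compute k and assimilation rates per incubation row; fit optionally.

    Rows that fail (e.g. filter DPM at or above tracer DPM) are reported
    with their line numbers and do not stop the remaining rows.  When at
    least ``fit_degree + 1`` distinct temperatures are present, a
    polynomial temperature-response fit and its interior peak are
    written to the fit report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = rates.read_incubations(incubations_path)
    ok_records, ks, assims, errors = [], [], [], []
    for i, rec in enumerate(records):
        try:
            k = rates.turnover_k(rec, subtract_control=subtract_control)
            a = rates.assim_rate(rec, k=k) if rec.dic_mmol_per_l is not None else None
        except ValueError as exc:
            errors.append({"line": i + 2, "label": rec.label, "error": str(exc)})
            continue
        ok_records.append(rec)
        ks.append(k)
        assims.append(a)

    files = {"rates": outdir / "rates.tsv"}
    rates.write_rates(ok_records, ks, assims, files["rates"])

    fit_report: Optional[dict] = None
    temps = [(r.temperature_c, k) for r, k in zip(ok_records, ks)
             if r.temperature_c is not None]
    if fit_degree is not None and temps:
        resp = rates.TemperatureResponse(temps)
        if resp.n_distinct_temperatures > fit_degree:
            fit = rates.fit_polynomial(resp, fit_degree)
            fit_report = {
                "degree": fit.degree,
                "coefficients_ascending": list(fit.coefficients),
                "r2": fit.r2,
                "adjusted_r2": fit.adjusted_r2,
                "aicc": fit.aicc,
            }
            if fit.degree == 3:
                t_lo = min(resp.temperatures)
                t_hi = max(resp.temperatures)
                try:
                    fit_report["peak_temperature_c"] = rates.peak_temperature(
                        fit, (t_lo, t_hi)
                    )
                except ValueError:
                    fit_report["peak_temperature_c"] = None
            files["fit"] = outdir / "fit.json"
            files["fit"].write_text(json.dumps(fit_report, indent=2) + "\n")

    manifest = {
        "stage": "rates",
        "parameters": {"subtract_control": subtract_control, "fit_degree": fit_degree},
        "inputs": {"incubations": str(incubations_path)},
        "counters": {"rows_in": len(records), "rows_ok": len(ok_records),
                     "rows_failed": len(errors)},
        "row_errors": errors,
        "fit": fit_report,
        "files": {k: str(v) for k, v in files.items()},
    }
    _write_manifest(outdir, "manifest_rates.json", manifest)
    for err in errors:
        logger.warning("row %d (%s): %s", err["line"], err["label"], err["error"])
    return manifest


def run_report(outdir) -> str:
    """Assemble a plain-text digest of any manifests found in ``outdir``."""
    outdir = Path(outdir)
    lines = []
    for manifest_path in sorted(outdir.glob("manifest_*.json")):
        m = json.loads(manifest_path.read_text())
        lines.append(f"[{m['stage']}]")
        for key, val in m.get("counters", {}).items():
            lines.append(f"  {key}: {val}")
        if m.get("fit"):
            fit = m["fit"]
            lines.append(f"  fit degree {fit['degree']}: R²={fit['r2']:.4f}, "
                         f"adj R²={fit['adjusted_r2']:.4f}")
            if fit.get("peak_temperature_c") is not None:
                lines.append(f"  peak temperature: {fit['peak_temperature_c']:.2f} °C")
    report = "\n".join(lines) if lines else "no manifests found"
    (outdir / "report.txt").write_text(report + "\n")
    return report
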