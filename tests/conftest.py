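"""Shared fixtures: compact reference pairs, planted fields, read sets.

A short 200-nt mock reference (window 100–146, diagnostic base 123) keeps
fragment coverage of the diagnostic window high, so end-to-end tests get
valid bins from modest read counts; the full-length default (1500 nt,
window 907–953) is exercised separately.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from symbiospot import synthetic

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


SHORT_REF = dict(diagnostic_pos=123, window=(100, 146), length=200)


@pytest.fixture(scope="session")
def refs():
    """Default full-length reference pair."""
    return synthetic.make_reference_pair(seed=1)


@pytest.fixture(scope="session")
def short_refs():
    """Compact reference pair for coverage-hungry end-to-end tests."""
    return synthetic.make_reference_pair(seed=1, **SHORT_REF)


@pytest.fixture()
def mosaic_field():
    """100×100 grid split into two pure stripes (A then G)."""
    cfg = synthetic.FieldConfig(
        grid_width=100, grid_height=100, field_model="domain-mosaic",
        n_domains=2, seed=11,
    )
    return synthetic.simulate_field(cfg)


def make_sam(reads: synthetic.SimulatedReads, refs: synthetic.ReferencePair,
             path) -> None:
    """Idealised exact-matching aligner emitting the kept 47-nt region.

    A read whose sequence contains either reference's diagnostic window
    verbatim is written as a unique (NH:i:1), MAPQ 255, CIGAR 47M record
    whose query is the matched window; other reads are written with
    MAPQ 3 so they fail the alignment filter.  This mirrors the
    extraction convention the package's alignment mode ingests.
    """
    start0 = refs.window[0] - 1
    ref_name = "ref_16S"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{len(refs.seq_a)}\n")
        for name, r2 in zip(reads.names, reads.read2):
            for window in (refs.window_a, refs.window_g):
                i = r2.find(window)
                if i >= 0:
                    fh.write(
                        f"{name}\t0\t{ref_name}\t{start0 + 1}\t255\t47M\t*\t0\t0\t"
                        f"{r2[i:i + 47]}\t{'I' * 47}\tNH:i:1\n"
                    )
                    break
            else:
                fh.write(
                    f"{name}\t0\t{ref_name}\t{start0 + 1}\t3\t"
                    f"{len(r2)}M\t*\t0\t0\t{r2}\t{'I' * len(r2)}\tNH:i:1\n"
                )
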