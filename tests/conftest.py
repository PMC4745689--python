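"""Shared fixtures: the six-SNP candidate panel with its published genotype
tallies (n=100, two gene regions), built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from sdrsurv.io_cohort import GenotypeMatrix, SnpDef, SurvivalOutcome

#: (snp_id, gene, major, minor, (n_hom_major, n_het, n_hom_minor))
PANEL_COUNTS = [
    ("rs2071559", "VEGFR-2", "A", "G", (29, 49, 22)),
    ("rs2305948", "VEGFR-2", "C", "T", (89, 10, 1)),
    ("rs1870377", "VEGFR-2", "T", "A", (72, 25, 3)),
    ("rs11133360", "VEGFR-2", "T", "C", (30, 50, 20)),
    ("rs3751143", "P2X7R", "A", "C", (60, 30, 10)),
    ("rs208294", "P2X7R", "C", "T", (29, 48, 23)),
]

#: printed exact-HWE p-values and major-allele frequencies for the panel
PANEL_HWE_P = [0.8435, 0.2956, 0.7, 1.0, 0.0589, 0.6926]
PANEL_MAJOR_FREQ = [0.54, 0.94, 0.84, 0.55, 0.75, 0.53]


def build_panel_matrix(shuffle_seed: int | None = None) -> GenotypeMatrix:
    """GenotypeMatrix of 100 subjects whose per-SNP genotype tallies equal
    the published candidate-panel counts."""
    rng = np.random.default_rng(shuffle_seed) if shuffle_seed is not None else None
    panel = []
    cols = []
    for snp_id, gene, major, minor, (a, b, c) in PANEL_COUNTS:
        panel.append(
            SnpDef(snp_id=snp_id, gene=gene, allele_major=major, allele_minor=minor)
        )
        col = np.repeat([0, 1, 2], [a, b, c]).astype(np.int8)
        if rng is not None:
            rng.shuffle(col)
        cols.append(col)
    ids = [f"P{i + 1:03d}" for i in range(100)]
    return GenotypeMatrix(ids, panel, np.column_stack(cols))


@pytest.fixture(scope="session")
def panel_gm() -> GenotypeMatrix:
    return build_panel_matrix()


@pytest.fixture()
def toy_outcome() -> SurvivalOutcome:
    """Six subjects, tied month-resolution times, mixed censoring."""
    return SurvivalOutcome(
        [f"S{i}" for i in range(6)],
        np.array([5.0, 5.0, 8.0, 12.0, 12.0, 20.0]),
        np.array([1, 0, 1, 1, 1, 0]),
    )
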