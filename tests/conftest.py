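"""Shared fixtures: tiny genotype matrices and a reusable synthetic panel."""

from __future__ import annotations

import numpy as np
import pytest

from feralgen.genotype import GenotypeMatrix, VariantSite, build_windows
from feralgen.simulate import MosaicSpec, PanelModel, simulate_panel


def make_gm(
    dosage,
    samples=None,
    chrom: str = "chrI",
    contig_len: int | None = None,
    gq: int = 99,
    dp: int = 30,
) -> GenotypeMatrix:
    """Build a matrix from a (samples x sites) dosage array (-1 = missing)."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n_samples, n_sites = dosage.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    sites = [VariantSite(chrom=chrom, pos=10 * j) for j in range(n_sites)]
    return GenotypeMatrix(
        sites=sites,
        samples=list(samples),
        dosage=dosage,
        gq=np.full(dosage.shape, gq, dtype=np.int32),
        dp=np.full(dosage.shape, dp, dtype=np.int32),
        contigs={chrom: contig_len or (10 * n_sites + 10)},
    )


@pytest.fixture(scope="session")
def panel():
    """3 clades x 3 lineages x 3 members, 5000 sites over two contigs."""
    return simulate_panel(PanelModel(), seed=11)


@pytest.fixture(scope="session")
def panel_windows(panel):
    model = PanelModel()
    return build_windows(model.contigs, size=25_000, sites=panel.gm.sites)


@pytest.fixture(scope="session")
def mosaic_spec():
    return MosaicSpec(n_isolates=3, switch_prob=0.4, seed=7)
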