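import numpy as np
import pandas as pd
import pytest

from radpop.variant_io import GenotypeMatrix


def make_gm(calls, positions=None, contig="chr1", depth=None, sample_prefix="s",
            biallelic=None):
    """Build a GenotypeMatrix from a samples x sites array of dosages (-1 missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if np.isscalar(contig):
        contig = [contig] * n_sites
    if biallelic is None:
        biallelic = [True] * n_sites
    sites = pd.DataFrame({
        "contig": contig,
        "pos": positions,
        "ref": ["A"] * n_sites,
        "alt": ["C"] * n_sites,
        "biallelic_snp": biallelic,
    })
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n_samples)],
        sites=sites,
        calls=calls,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
    )


def panel_to_gm(panel):
    """Wrap a HaplotypePanel's dosages as a GenotypeMatrix (no missingness)."""
    sites = panel.sites.assign(ref="A", alt="C", biallelic_snp=True)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(panel.n_samples)],
        sites=sites,
        calls=panel.dosages(),
    )


@pytest.fixture(scope="session")
def decay_panel():
    """200-haplotype single-population panel at the reference retention rate."""
    from radpop.synthetic_data import SimConfig, simulate

    cfg = SimConfig(
        seed=2, n_populations=1, n_samples_per_pop=100, n_contigs=4,
        contig_length=10_000, retention_per_bp=0.99943, fst_target=0.0,
        missing_rate=0.0, n_spiked_pairs=0, n_spiked_diff_sites=0,
    )
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """A small structured simulation emitted to disk, shared across tests."""
    from radpop.synthetic_data import SimConfig, simulate, emit_fixtures

    cfg = SimConfig(seed=5)
    panel = simulate(cfg)
    out = tmp_path_factory.mktemp("fixtures")
    paths = emit_fixtures(panel, cfg, out)
    return cfg, panel, paths
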