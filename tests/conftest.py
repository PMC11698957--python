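import pytest
from hypothesis import HealthCheck, settings

from smmkit import synthetic

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SimConfig(seed=0)


@pytest.fixture(scope="session")
def sc_dataset(default_config):
    """One shared synthetic single-cell dataset (counts, TCR, BCR)."""
    return synthetic.generate_sc_repertoire_dataset(default_config)


@pytest.fixture(scope="session")
def balanced_de_pipeline():
    """Standard tumor-cell DE pipeline: QC filter, fixed-depth downsampling
    (target below typical cell depth, as in the trial's design), balanced
    per-patient subsample, Wilcoxon + BH."""

    def run(adata, seed, quota=150, target=500, group_a="non_progressor"):
        from smmkit import de, qc

        keep = qc.filter_cells_qc(qc.compute_qc_metrics(adata))
        tum = adata[keep & adata.obs["truth_is_tumor"].to_numpy()]
        ds = qc.downsample_reads_per_cell(tum, target=target, seed=seed)
        spec = de.BalanceSpec(
            {"progressor": quota, "non_progressor": quota}, seed=seed
        )
        idx = de.draw_balanced_subsample(
            ds.obs["patient"].to_numpy(), ds.obs["group"].to_numpy(), spec
        )
        sub = ds[idx]
        return de.wilcoxon_bh_de(sub, sub.obs["group"].to_numpy(), group_a=group_a)

    return run
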