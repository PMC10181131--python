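import pandas as pd
import pytest

from tetrafinger.datasets import load_parms_snp_panel, panel_counts
from tetrafinger.marker_stats import stats_from_counts
from tetrafinger.synthetic_data import simulate_cohort_vcf


@pytest.fixture(scope="session")
def panel() -> pd.DataFrame:
    """Published 71-marker dosage-class table with printed statistics."""
    return load_parms_snp_panel()


@pytest.fixture(scope="session")
def panel_stats(panel) -> pd.DataFrame:
    """Marker statistics recomputed from the published class counts."""
    return stats_from_counts(panel_counts())


@pytest.fixture(scope="session")
def cohort_fixture(tmp_path_factory):
    """Simulated cohort VCF with 5 planted perfect SNPs and 3 flanking
    violators among 50 sites."""
    out = tmp_path_factory.mktemp("cohort")
    vcf, fasta, truth = simulate_cohort_vcf(
        n_samples=50, n_sites=50, planted_perfect=5, flank_violators=3,
        mean_depth=30.0, seed=20240915, out_dir=out)
    return vcf, fasta, truth
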