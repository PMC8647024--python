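import numpy as np
import pandas as pd
import pytest

from aneupr.io import ArmTable, ExpressionMatrix, SampleMetadata, SegmentedProfile
from aneupr.simulate import CohortConfig, default_arm_table, simulate_cohort


@pytest.fixture(scope="session")
def arms() -> ArmTable:
    return default_arm_table()


@pytest.fixture(scope="session")
def arm_dict(arms):
    """Plain mapping form of the arm table, for the brute-force oracles."""
    return {
        chrom: {
            "p": arms.arm_interval(chrom, "p"),
            "q": arms.arm_interval(chrom, "q"),
        }
        for chrom in arms.table.index
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort (segments realized)."""
    cfg = CohortConfig(
        seed=42,
        n_tumor_types=3,
        samples_per_type=40,
        normals_per_type=10,
        n_differential_types=2,
    )
    return simulate_cohort(cfg)


def toy_profile(sample_id, rows):
    return SegmentedProfile(
        sample_id=sample_id,
        regions=pd.DataFrame(rows, columns=["chromosome", "start", "end", "log2fc"]),
    )


@pytest.fixture
def toy_expression():
    genes = ["GZMA", "PRF1", "A", "B"]
    data = pd.DataFrame(
        [[4.0, 1.0, 9.0], [9.0, 1.0, 4.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
        index=pd.Index(genes, name="gene"),
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def toy_metadata():
    idx = pd.Index(["s1", "s2", "s3"], name="sample")
    return SampleMetadata(
        pd.DataFrame({"tumor_type": "TT", "is_tumor": True}, index=idx)
    )


def make_metadata(samples, tumor_type="TT", is_tumor=True, **columns):
    idx = pd.Index(list(samples), name="sample")
    base = {"tumor_type": tumor_type, "is_tumor": is_tumor}
    base.update(columns)
    return SampleMetadata(pd.DataFrame(base, index=idx))
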