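import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cdmkit import io, simulate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_dataset_files(tmp_path):
    """3-probe x 4-sample expression TSV plus metadata (2 control / 2 disease)."""
    matrix = tmp_path / "expr.tsv"
    matrix.write_text(
        "probe_id\ts1\ts2\ts3\ts4\n"
        "p1\t10.0\t12.0\t20.0\t22.0\n"
        "p2\t5.0\t6.0\t5.5\t6.5\n"
        "p3\t100.0\t110.0\t90.0\t95.0\n"
    )
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "sample_id\tcondition\tsubset\tplatform\n"
        "s1\tcontrol\tA\tPLAT1\n"
        "s2\tcontrol\tA\tPLAT1\n"
        "s3\tdisease\tA\tPLAT1\n"
        "s4\tdisease\tA\tPLAT1\n"
    )
    return matrix, meta


def make_dataset(values, condition, subset, platform_id="P", probes=None):
    """Build an ExpressionDataset from a plain array and label lists."""
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i + 1}" for i in range(values.shape[0])]
    samples = [f"s{j + 1}" for j in range(values.shape[1])]
    return io.ExpressionDataset(
        platform_id=platform_id,
        intensities=pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                                 columns=samples),
        condition=pd.Series(condition, index=samples),
        subset=pd.Series(subset, index=samples),
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact multi-platform study shared by read-only tests."""
    return simulate.generate_multiplatform_study(n_genes=600, seed=42)
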