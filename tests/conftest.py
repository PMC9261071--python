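import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cpmct.dataio import ExpressionDataset
from cpmct.lmm import LmmFit, fit_cell_means_lmm
from cpmct.simulate import ScenarioSpec, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(values_by_cluster: dict[str, tuple[str, list[float]]]) -> ExpressionDataset:
    """Build a dataset from {cluster: (timepoint, values)} by hand."""
    rows = []
    for cluster, (tp, values) in values_by_cluster.items():
        for i, v in enumerate(values, start=1):
            rows.append((float(v), np.nan, tp, cluster, f"{cluster}_p{i}"))
    obs = pd.DataFrame(
        rows, columns=["value", "raw_value", "timepoint", "cluster", "unit"]
    )
    order = obs["timepoint"].drop_duplicates().tolist()
    return ExpressionDataset(obs, order)


def make_fit(
    beta: np.ndarray,
    vcov: np.ndarray,
    df_residual: int = 100,
    timepoint_order: list[str] | None = None,
) -> LmmFit:
    """Synthetic LmmFit for testing downstream modules in isolation."""
    beta = np.asarray(beta, dtype=float)
    T = len(beta)
    return LmmFit(
        beta=beta,
        vcov_beta=np.asarray(vcov, dtype=float),
        sigma2_cluster=1.0,
        sigma2_resid=1.0,
        reml_loglik=0.0,
        df_residual=df_residual,
        df_containment=max(df_residual // 10, 1),
        n_per_timepoint=np.full(T, 10),
        timepoint_order=timepoint_order or [f"t{i + 1}" for i in range(T)],
        singular=False,
        converged=True,
    )


def make_sci(estimates, lowers, uppers, ctype="sequen", alpha=0.05):
    """Hand-built SimultaneousCI for decision-layer tests."""
    from cpmct.simci import SimultaneousCI

    estimates = np.asarray(estimates, dtype=float)
    lowers = np.asarray(lowers, dtype=float)
    uppers = np.asarray(uppers, dtype=float)
    se = (uppers - lowers) / 4.0  # arbitrary positive widths
    labels = (
        [f"{i + 2}-{i + 1}" for i in range(len(estimates))]
        if ctype == "sequen"
        else [f"C{i + 1}" for i in range(len(estimates))]
    )
    rows = pd.DataFrame(
        {
            "label": labels,
            "estimate": estimates,
            "se": se,
            "lower": lowers,
            "upper": uppers,
            "t_statistic": estimates / np.where(se > 0, se, 1.0),
            "adjusted_p": np.full(len(estimates), np.nan),
        }
    )
    return SimultaneousCI(
        rows=rows,
        crit=2.0,
        corr=np.eye(len(estimates)),
        df=100.0,
        alpha=alpha,
        mc_error=0.0,
        seed=0,
        ctype=ctype,
    )


@pytest.fixture(scope="session")
def stepwise_ds():
    """Two upward steps of height 10 at time points 5 and 9 (fixed seed)."""
    return simulate_dataset(ScenarioSpec(kind="stepwise_increase", n_changepoints=2, seed=42))


@pytest.fixture(scope="session")
def stepwise_fit(stepwise_ds):
    return fit_cell_means_lmm(stepwise_ds)


@pytest.fixture(scope="session")
def partly_dropped_ds():
    """Transient drop of 10 at time points 6-7 (fixed seed)."""
    return simulate_dataset(ScenarioSpec(kind="partly_dropped", seed=1))


@pytest.fixture(scope="session")
def partly_dropped_fit(partly_dropped_ds):
    return fit_cell_means_lmm(partly_dropped_ds)


@pytest.fixture(scope="session")
def no_change_ds():
    return simulate_dataset(ScenarioSpec(kind="no_change", seed=11))
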