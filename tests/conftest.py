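import numpy as np
import pandas as pd
import pytest

from reopair.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """Mid-sized cohort with every planted signal, shared across tests."""
    cfg = CohortConfig(n_samples=300, n_genes=120, n_planted_pairs=5,
                       n_dm_genes=40, n_amplified_genes=10,
                       n_mutation_genes=10, hazard_ratio=6.0,
                       censor_rate=0.3, reo_fidelity=0.95, seed=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_labels(demo_cohort):
    return pd.Series(demo_cohort.truth.sample_risk_labels)


def brute_force_c_index(risk, time, event):
    """Pair-enumeration oracle for Harrell's C-index.

    Comparable: strictly smaller time ends in an event. Concordant:
    earlier failure has the larger risk score; ties in score count 1/2.
    """
    risk, time, event = map(np.asarray, (risk, time, event))
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or not (time[i] < time[j] and event[i] == 1):
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den


def breslow_grid_beta(x, time, event, lo=-10.0, hi=10.0, step=1e-4):
    """Dense grid-search oracle for the univariate Breslow Cox MLE
    (vectorized over the beta grid; fine for tiny n)."""
    x, time, event = map(np.asarray, (x, time, event))
    betas = np.arange(lo, hi + step, step)
    ll = np.zeros_like(betas)
    for i in range(len(time)):
        if event[i]:
            risk = np.exp(betas[:, None] * x[time >= time[i]]).sum(axis=1)
            ll += betas * x[i] - np.log(risk)
    return float(betas[np.argmax(ll)])
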