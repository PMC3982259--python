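import numpy as np
import pytest

from fsvmcip import Dataset, HyperParams, KernelSpec
from fsvmcip.locality import GraphParams
from fsvmcip.membership import MembershipParams


def random_dataset(rng, n_pos=None, n_neg=None, dim=None, separation=2.0):
    """Small random two-class Gaussian dataset in canonical order."""
    n_pos = n_pos or int(rng.integers(3, 7))
    n_neg = n_neg or int(rng.integers(2, 5))
    dim = dim or int(rng.integers(1, 5))
    Xp = rng.normal(size=(n_pos, dim))
    Xn = rng.normal(size=(n_neg, dim))
    Xn[:, 0] += separation
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    return Dataset(X=X, y=y)


def random_hyperparams(rng, ds, mu, eta_choices=(0.0, 0.5, 2.0)):
    """Feasible hyperparameters: nu drawn strictly inside both classes'
    total cost-mass caps."""
    v1 = float(rng.choice([0.005, 0.01, 0.05]))
    v2 = float(rng.choice([0.005, 0.01, 0.05]))
    cap_pos = mu[ds.pos_mask].sum() / (v1 * ds.m1)
    cap_neg = mu[~ds.pos_mask].sum() / (v2 * ds.m2)
    nu = float(rng.uniform(0.3, 0.9)) * min(cap_pos, cap_neg)
    k = int(rng.integers(1, 3))
    t = float(rng.choice([0.5, 1.0, 2.0]))
    lam = float(rng.uniform(0.1, 1.0))
    return HyperParams(
        nu=nu,
        v1=v1,
        v2=v2,
        eta=float(rng.choice(eta_choices)),
        graph=GraphParams(k=k, t=t),
        membership=MembershipParams(family="exponential", lam=lam),
    )


def random_kernel_spec(rng, X):
    tau2 = float(np.mean(np.sum(X**2, axis=1)))
    return KernelSpec(name="rbf", sigma=tau2 * float(rng.choice([0.5, 1.0, 2.0])))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
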