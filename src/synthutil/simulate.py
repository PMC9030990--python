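"""Simulate "real" health-like tabular datasets with known structure.

Real clinical datasets are heterogeneous: a few hundred to a few thousand
patients, a mix of skewed labs and demographic categoricals, latent
correlation among variables, and a binary or multicategory outcome driven
by the predictors through a logistic link.  :func:`simulate_real` emulates
those features with a Gaussian copula: a latent multivariate normal draw is
pushed through per-column monotone transforms (continuous) or quantile
slicing (categorical), and the outcome is drawn from a multinomial-logistic
link on the standardized encoded predictors.  Everything is a deterministic
function of the spec's seed, so any dataset of an experiment can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .tabular import ColumnMeta, TabularDataset, encode

__all__ = ["RealDataSpec", "simulate_real", "random_real_spec", "perturb_dataset"]


@dataclass
class RealDataSpec:
    """Recipe for one simulated "real" dataset.

    ``latent_correlation`` is the copula correlation matrix over the
    ``n_continuous + len(categorical_level_counts)`` latent coordinates
    (symmetric positive-definite, unit diagonal).  ``outcome_coefficients``
    acts on the standardized/one-hot encoded predictors; with ``K`` outcome
    levels the class-``k`` logit is ``s_k * (x @ beta)`` with ``s_k``
    equally spaced in [-1, 1], which is the ordinary logistic link at K=2
    and yields predictor-independent outcomes when beta is zero.
    """

    n_rows: int
    n_continuous: int
    categorical_level_counts: list[int]
    latent_correlation: np.ndarray
    outcome_levels: int
    outcome_coefficients: np.ndarray
    outcome_intercept: float = 0.0
    seed: int = 0
    name: str = "sim"

    @property
    def n_latent(self) -> int:
        return self.n_continuous + len(self.categorical_level_counts)

    def validate(self) -> None:
        R = np.asarray(self.latent_correlation, dtype=float)
        if R.shape != (self.n_latent, self.n_latent):
            raise ValueError("latent_correlation dimension mismatch")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("latent_correlation must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValueError("latent_correlation is not positive-definite") from exc
        if self.outcome_levels < 2:
            raise ValueError("outcome needs >= 2 levels")


# transforms cycled over continuous columns: identity-like, lognormal-like,
# shifted/rescaled — all monotone in the latent coordinate
_TRANSFORMS = (
    lambda z: 50.0 + 10.0 * z,
    lambda z: np.exp(z),
    lambda z: 100.0 + 25.0 * z,
)


def simulate_real(spec: RealDataSpec) -> TabularDataset:
    """Draw one dataset from the spec's Gaussian-copula generative model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R = np.asarray(spec.latent_correlation, dtype=float)
    Z = rng.multivariate_normal(np.zeros(spec.n_latent), R, size=spec.n_rows,
                                method="cholesky")

    data: dict[str, np.ndarray | list] = {}
    metas: list[ColumnMeta] = []
    for j in range(spec.n_continuous):
        name = f"x{j}"
        data[name] = _TRANSFORMS[j % len(_TRANSFORMS)](Z[:, j])
        metas.append(ColumnMeta(name, "continuous"))
    for k, n_lev in enumerate(spec.categorical_level_counts):
        name = f"c{k}"
        u = norm.cdf(Z[:, spec.n_continuous + k])
        idx = np.minimum((u * n_lev).astype(int), n_lev - 1)
        levels = tuple(f"l{i}" for i in range(n_lev))
        data[name] = [levels[i] for i in idx]
        metas.append(ColumnMeta(name, "categorical", levels=levels))

    out_levels = tuple(f"y{i}" for i in range(spec.outcome_levels))
    # placeholder outcome so the predictors can be encoded, then overwritten
    df = pd.DataFrame(data)
    df["y"] = out_levels[0]
    metas.append(ColumnMeta("y", "categorical", levels=out_levels, is_outcome=True))
    ds = TabularDataset(metas, df, spec.name)

    X = encode(ds, include_outcome=False).matrix
    beta = np.asarray(spec.outcome_coefficients, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(
            f"outcome_coefficients has length {beta.shape}, encoded predictors "
            f"have dimension {X.shape[1]}"
        )
    eta = X @ beta + spec.outcome_intercept
    K = spec.outcome_levels
    if K == 2:
        p1 = expit(eta)
        y_idx = (rng.random(spec.n_rows) < p1).astype(int)
    else:
        s = np.linspace(-1.0, 1.0, K)
        logits = np.outer(eta, s)
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        cum = np.cumsum(P, axis=1)
        u = rng.random(spec.n_rows)
        y_idx = (u[:, None] > cum).sum(axis=1)
    ds.values["y"] = [out_levels[i] for i in y_idx]
    ds.validate()
    return ds


def _random_correlation(d: int, rng: np.random.Generator,
                        strength: tuple[float, float] = (0.4, 0.8)) -> np.ndarray:
    """Random correlation matrix with non-trivial off-diagonals.

    A random Wishart-style correlation is shrunk toward the identity by a
    weight drawn from ``strength``; the result is always PD.
    """
    A = rng.standard_normal((d, d + 2))
    S = A @ A.T
    dinv = 1.0 / np.sqrt(np.diag(S))
    C = S * np.outer(dinv, dinv)
    w = rng.uniform(*strength)
    R = w * C + (1 - w) * np.eye(d)
    dinv = 1.0 / np.sqrt(np.diag(R))
    return R * np.outer(dinv, dinv)


def random_real_spec(
    seed: int,
    n_rows: int | None = None,
    n_rows_range: tuple[int, int] = (500, 2000),
    outcome_levels: int = 2,
    signal_sd: float = 1.5,
    name: str | None = None,
) -> RealDataSpec:
    """Draw a heterogeneous dataset recipe at desk scale.

    Column counts, level counts, the latent correlation and the outcome
    coefficients all vary with the seed, emulating the heterogeneity of a
    basket of observational health datasets.  ``signal_sd`` scales the
    coefficient vector so the linear predictor has roughly that standard
    deviation, giving the real-data logistic model clear but imperfect
    discrimination (AUROC around 0.8).
    """
    rng = np.random.default_rng(seed)
    n = int(n_rows) if n_rows is not None else int(rng.integers(*n_rows_range))
    n_cont = int(rng.integers(2, 6))
    n_cat = int(rng.integers(1, 4))
    level_counts = [int(rng.integers(2, 5)) for _ in range(n_cat)]
    d_lat = n_cont + n_cat
    R = _random_correlation(d_lat, rng)
    # outcome coefficients: free for continuous predictors; an ordered ramp
    # over the levels of each categorical (ordered level effects, as for
    # dose/stage/age-group variables) so the outcome's dependence on every
    # predictor is monotone in that predictor's latent coordinate
    parts = [rng.standard_normal(n_cont)]
    for k_lev in level_counts:
        slope = rng.standard_normal()
        parts.append(slope * np.linspace(-1.0, 1.0, k_lev))
    beta = np.concatenate(parts)
    beta *= signal_sd / max(np.linalg.norm(beta) / np.sqrt(2.0), 1e-12)
    return RealDataSpec(
        n_rows=n,
        n_continuous=n_cont,
        categorical_level_counts=level_counts,
        latent_correlation=R,
        outcome_levels=outcome_levels,
        outcome_coefficients=beta,
        seed=int(rng.integers(0, 2**31 - 1)),
        name=name or f"sim{seed}",
    )


def perturb_dataset(ds: TabularDataset, noise_scale: float, flip_prob: float,
                    seed: int) -> TabularDataset:
    """Degrade a dataset copy: Gaussian noise on continuous columns (scaled
    by each column's SD) and random level flips on categorical columns.

    Used to verify that every utility metric responds monotonically to
    increasing departure from the real data.
    """
    rng = np.random.default_rng(seed)
    out = ds.copy()
    for c in out.columns:
        if c.kind == "continuous":
            x = out.values[c.name].to_numpy(dtype=float)
            sd = np.std(x)
            out.values[c.name] = x + rng.normal(0.0, noise_scale * max(sd, 1e-12),
                                                size=len(x))
        else:
            vals = out.values[c.name].to_numpy(dtype=object).copy()
            flip = rng.random(len(vals)) < flip_prob
            vals[flip] = rng.choice(c.levels, size=int(flip.sum()))
            out.values[c.name] = vals
    out.validate()
    return out
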