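"""Parametric empirical-Bayes ComBat for vectorized connectivity cohorts.

The model treats each triangle entry (edge) as a feature and each subject as a
sample. For feature g of subject j at site i,

    y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg,

where X carries the biological covariates to be *retained* (age, sex),
gamma_ig is the additive and delta_ig the multiplicative site effect, and
eps ~ N(0, sigma_g^2). Site parameters are estimated per feature, then shrunk
across features toward site-level priors (normal on gamma, inverse-gamma on
delta^2) by the standard empirical-Bayes fixed-point iteration. The adjusted
data subtract gamma* and divide by delta*, then restore the grand mean and the
covariate contribution, so age/sex-attributable variance survives harmonization.

Features with zero variance across the whole cohort (edges absent in every
subject) cannot be modeled; they are recorded in a mask and passed through
untouched so the matrix layout survives devectorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from connharm.io import VectorizedCohort


class CombatError(ValueError):
    """Raised for inputs the ComBat model cannot be fitted to or applied on."""


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = float(np.mean(delta_hat)), float(np.var(delta_hat, ddof=1))
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = float(np.mean(delta_hat)), float(np.var(delta_hat, ddof=1))
    return (m * s2 + m**3) / s2


@dataclass
class CombatModel:
    """Fitted standardization and empirical-Bayes site parameters.

    Per modeled feature: grand mean ``alpha``, covariate coefficients ``beta``
    (columns age, sex), pooled variance ``var_pooled``; per (site, feature):
    raw estimates ``gamma_hat``/``delta_hat_sq`` and shrunken ``gamma_star``/
    ``delta_star_sq``. ``mask`` flags zero-variance features excluded from the
    model. Arrays are indexed over *all* features, with NaN at masked rows for
    the per-feature parameters.
    """

    sites: list[int]
    n_per_site: dict[int, int]
    mask: np.ndarray  # True = zero-variance, excluded
    alpha: np.ndarray
    beta: np.ndarray  # (f, 2)
    var_pooled: np.ndarray
    gamma_hat: dict[int, np.ndarray]
    delta_hat_sq: dict[int, np.ndarray]
    gamma_bar: dict[int, float]
    tau_sq: dict[int, float]
    a_prior: dict[int, float]
    b_prior: dict[int, float]
    gamma_star: dict[int, np.ndarray]
    delta_star_sq: dict[int, np.ndarray]
    eb: bool = True
    n_iter: dict[int, int] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.alpha)

    def save(self, path: str | Path) -> None:
        """Write a feature-indexed parameter table (CSV with a '#' header block)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cols: dict[str, np.ndarray] = {
            "mask": self.mask.astype(int),
            "alpha": self.alpha,
            "beta_age": self.beta[:, 0],
            "beta_sex": self.beta[:, 1],
            "var_pooled": self.var_pooled,
        }
        for i in self.sites:
            cols[f"gamma_hat_site{i}"] = self.gamma_hat[i]
            cols[f"delta_hat_sq_site{i}"] = self.delta_hat_sq[i]
            cols[f"gamma_star_site{i}"] = self.gamma_star[i]
            cols[f"delta_star_sq_site{i}"] = self.delta_star_sq[i]
        df = pd.DataFrame(cols)
        with open(path, "w") as fh:
            fh.write(f"# combat_model eb={int(self.eb)}\n")
            fh.write(f"# sites={','.join(str(i) for i in self.sites)}\n")
            fh.write(f"# n_per_site={','.join(str(self.n_per_site[i]) for i in self.sites)}\n")
            for i in self.sites:
                fh.write(
                    f"# hyper_site{i}="
                    f"{self.gamma_bar[i]!r},{self.tau_sq[i]!r},"
                    f"{self.a_prior[i]!r},{self.b_prior[i]!r}\n"
                )
            df.to_csv(fh, index_label="feature")

    @classmethod
    def load(cls, path: str | Path) -> "CombatModel":
        header: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, index_col="feature")
        sites = [int(x) for x in header["sites"].split(",")]
        n_per = dict(zip(sites, (int(x) for x in header["n_per_site"].split(","))))
        hyper = {i: [float(x) for x in header[f"hyper_site{i}"].split(",")] for i in sites}
        return cls(
            sites=sites,
            n_per_site=n_per,
            mask=df["mask"].to_numpy(bool),
            alpha=df["alpha"].to_numpy(float),
            beta=df[["beta_age", "beta_sex"]].to_numpy(float),
            var_pooled=df["var_pooled"].to_numpy(float),
            gamma_hat={i: df[f"gamma_hat_site{i}"].to_numpy(float) for i in sites},
            delta_hat_sq={i: df[f"delta_hat_sq_site{i}"].to_numpy(float) for i in sites},
            gamma_bar={i: hyper[i][0] for i in sites},
            tau_sq={i: hyper[i][1] for i in sites},
            a_prior={i: hyper[i][2] for i in sites},
            b_prior={i: hyper[i][3] for i in sites},
            gamma_star={i: df[f"gamma_star_site{i}"].to_numpy(float) for i in sites},
            delta_star_sq={i: df[f"delta_star_sq_site{i}"].to_numpy(float) for i in sites},
            eb=bool(int(header["combat_model eb"])),
        )


def _design(v: VectorizedCohort, sites: list[int]) -> np.ndarray:
    onehot = np.column_stack([(v.batch == i).astype(float) for i in sites])
    return np.hstack([onehot, v.covariates])


def _eb_iterate(
    z_site: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat_sq: np.ndarray,
    gamma_bar: float,
    tau_sq: float,
    a: float,
    b: float,
    conv: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fixed-point iteration for the EB posterior means gamma*, delta^2*."""
    n = z_site.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta_hat_sq.copy()
    for it in range(1, max_iter + 1):
        g_new = (n * tau_sq * gamma_hat + d_old * gamma_bar) / (n * tau_sq + d_old)
        sum2 = ((z_site - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            float(np.max(np.abs(g_new - g_old))), float(np.max(np.abs(d_new - d_old)))
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old, it


def combat_fit(
    v: VectorizedCohort, eb: bool = True, conv: float = 1e-6, max_iter: int = 1000
) -> CombatModel:
    """Fit the ComBat location/scale model on a two-site vectorized cohort.

    Parameters
    ----------
    v : VectorizedCohort
        Features-by-subjects table with batch vector and (age, sex) covariates.
    eb : bool
        Shrink site parameters with parametric empirical Bayes (the standard
        variant). With ``eb=False`` the raw per-site estimates are used, which
        equalizes per-feature site means exactly on the training data.
    conv, max_iter
        Convergence threshold (max absolute change of gamma*, delta^2*) and
        iteration cap of the EB fixed point.
    """
    y = np.asarray(v.features, dtype=float)
    sites = sorted(set(int(b) for b in v.batch))
    if len(sites) < 2:
        raise CombatError("combat_fit needs at least 2 sites")
    n_per = {i: int((v.batch == i).sum()) for i in sites}
    for i, n in n_per.items():
        if n < 3:
            raise CombatError(f"site {i} has only {n} subjects; need >= 3")
    n_total = y.shape[1]

    mask = y.var(axis=1) == 0.0
    if mask.all():
        raise CombatError("all features have zero variance")
    ym = y[~mask]

    x = _design(v, sites)
    b_hat, *_ = np.linalg.lstsq(x, ym.T, rcond=None)  # (2 + 2, f_modeled)
    weights = np.array([n_per[i] / n_total for i in sites])
    grand_mean = weights @ b_hat[: len(sites)]
    beta = b_hat[len(sites):]  # (2, f_modeled)
    stand_mean = grand_mean[:, None] + (v.covariates @ beta).T  # (f_modeled, s)
    resid = ym - (x @ b_hat).T
    var_pooled = (resid**2).mean(axis=1)
    if np.any(var_pooled <= 0):
        # residual-degenerate features behave like zero-variance ones
        extra = np.zeros_like(mask)
        extra[np.flatnonzero(~mask)[var_pooled <= 0]] = True
        mask = mask | extra
        ym = y[~mask]
        b_hat, *_ = np.linalg.lstsq(x, ym.T, rcond=None)
        grand_mean = weights @ b_hat[: len(sites)]
        beta = b_hat[len(sites):]
        stand_mean = grand_mean[:, None] + (v.covariates @ beta).T
        resid = ym - (x @ b_hat).T
        var_pooled = (resid**2).mean(axis=1)

    z = (ym - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat, delta_hat_sq = {}, {}
    gamma_bar, tau_sq, a_prior, b_prior = {}, {}, {}, {}
    gamma_star, delta_star_sq, n_iter = {}, {}, {}
    for i in sites:
        zi = z[:, v.batch == i]
        gh = zi.mean(axis=1)
        dh = zi.var(axis=1, ddof=1)
        gamma_hat[i], delta_hat_sq[i] = gh, dh
        gamma_bar[i] = float(gh.mean())
        tau_sq[i] = float(gh.var(ddof=1))
        a_prior[i] = _aprior(dh)
        b_prior[i] = _bprior(dh)
        if eb:
            gs, ds, it = _eb_iterate(
                zi, gh, dh, gamma_bar[i], tau_sq[i], a_prior[i], b_prior[i], conv, max_iter
            )
        else:
            gs, ds, it = gh.copy(), dh.copy(), 0
        if np.any(ds <= 0):
            raise CombatError(f"site {i}: nonpositive delta^2*; data too degenerate to model")
        gamma_star[i], delta_star_sq[i], n_iter[i] = gs, ds, it

    def expand(arr: np.ndarray) -> np.ndarray:
        full = np.full(y.shape[0], np.nan)
        full[~mask] = arr
        return full

    return CombatModel(
        sites=sites,
        n_per_site=n_per,
        mask=mask,
        alpha=expand(grand_mean),
        beta=np.column_stack([expand(beta[0]), expand(beta[1])]),
        var_pooled=expand(var_pooled),
        gamma_hat={i: expand(gamma_hat[i]) for i in sites},
        delta_hat_sq={i: expand(delta_hat_sq[i]) for i in sites},
        gamma_bar=gamma_bar,
        tau_sq=tau_sq,
        a_prior=a_prior,
        b_prior=b_prior,
        gamma_star={i: expand(gamma_star[i]) for i in sites},
        delta_star_sq={i: expand(delta_star_sq[i]) for i in sites},
        eb=eb,
        n_iter=n_iter,
    )


def combat_apply(model: CombatModel, v: VectorizedCohort) -> VectorizedCohort:
    """Adjust a vectorized cohort with a fitted ComBat model.

    Modeled features are standardized with the model's grand mean, covariate
    coefficients and pooled variance, adjusted to (z - gamma*)/delta*, then
    de-standardized (adding back alpha + X beta). Masked features pass through
    unchanged. The output may contain negatives; clamping happens at
    devectorization.
    """
    y = np.asarray(v.features, dtype=float)
    if y.shape[0] != model.n_features:
        raise CombatError(
            f"feature-count mismatch: model has {model.n_features}, data has {y.shape[0]}"
        )
    unknown = set(int(b) for b in v.batch) - set(model.sites)
    if unknown:
        raise CombatError(f"data contain sites the model was not fitted on: {sorted(unknown)}")
    keep = ~model.mask
    ym = y[keep]
    stand_mean = model.alpha[keep][:, None] + (v.covariates @ model.beta[keep].T).T
    sd = np.sqrt(model.var_pooled[keep])[:, None]
    z = (ym - stand_mean) / sd
    adj = np.empty_like(z)
    for i in model.sites:
        cols = v.batch == i
        if not cols.any():
            continue
        g = model.gamma_star[i][keep][:, None]
        d = np.sqrt(model.delta_star_sq[i][keep])[:, None]
        adj[:, cols] = (z[:, cols] - g) / d
    out = y.copy()
    out[keep] = adj * sd + stand_mean
    return VectorizedCohort(
        features=out,
        index_map=v.index_map,
        batch=v.batch,
        covariates=v.covariates,
        subject_ids=list(v.subject_ids),
        weighting=v.weighting,
    )
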