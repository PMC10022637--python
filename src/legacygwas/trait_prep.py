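"""Phenotype preparation: from raw multi-environment records to scan-ready vectors.

Gene-bank legacy records accumulate over decades at many stations, so a
variety's raw mean confounds its genetics with where and when it happened
to be grown.  ``adjust_env`` removes this by fitting a linear mixed model
with variety as a fixed effect and the location-by-year combination as an
iid Gaussian random effect, returning per-variety BLUEs.  The module also
covers the bookkeeping around it: converting heading dates to days after
July 1, classifying traits as binary vs quantitative from their value
distribution, binarizing ordinal color scales, z-scoring phenotypes so
marker effects are comparable across traits, and pairwise-complete Pearson
correlations between traits.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import TraitTable
from .mixed_model_scan import reml_fit

log = logging.getLogger(__name__)

PROVENANCES = ("raw", "env_adjusted", "standardized", "binarized")


@dataclass
class PhenotypeVector:
    """One trait's per-variety values, with type and processing provenance."""

    values: pd.Series  # index = variety
    trait_name: str
    trait_type: str = "quantitative"
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait type {self.trait_type!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.trait_type == "binary":
            v = self.values.dropna()
            if not v.isin([0.0, 1.0]).all():
                raise ValueError("binary phenotype must be coded 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variety": self.values.index, "value": self.values.values})


# ---------------------------------------------------------------------------

def heading_days(month: int, day: int) -> int:
    """Days after July 1 for a heading date in the growing season.

    July 1 maps to 0; later dates are positive, earlier ones negative.  All
    dates are treated as falling in the same (non-leap reference) year.
    """
    try:
        date = datetime.date(2001, month, day)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid date month={month} day={day}") from exc
    return (date - datetime.date(2001, 7, 1)).days


def classify_trait_type(values, modal_fraction_cutoff: float = 0.8) -> str:
    """Designate a trait binary or quantitative from its value distribution.

    A trait is binary-like when a single level dominates (modal fraction at
    or above the cutoff — "extremely unidirectional" scoring) or when it
    takes exactly two distinct levels; otherwise quantitative.  Invariant
    to relabeling of levels.
    """
    v = pd.Series(values).dropna()
    if len(v) < 10:
        raise ValueError("need >= 10 non-missing values to classify")
    counts = v.value_counts()
    if len(counts) == 1:
        raise ValueError("no variation: constant trait cannot be classified")
    if len(counts) == 2:
        return "binary"
    if counts.iloc[0] / len(v) >= modal_fraction_cutoff:
        return "binary"
    return "quantitative"


def binarize(values: pd.Series, split, trait_name: str = "trait") -> PhenotypeVector:
    """0/1-code a trait.

    ``split`` is either ``("threshold", t)`` — value <= t maps to 0, above
    to 1 (e.g. color score 1 = non-colored vs 2-9 = colored uses t = 1; the
    light/dark tone split within colored lines uses t = 4) — or
    ``"modal_vs_rest"``, mapping the most frequent level to 0.
    """
    v = pd.Series(values).astype(float)
    obs = v.dropna()
    if isinstance(split, str):
        if split != "modal_vs_rest":
            raise ValueError(f"unknown split {split!r}")
        modal = obs.value_counts().index[0]
        coded = (v != modal).astype(float).where(v.notna())
    else:
        kind, t = split
        if kind != "threshold":
            raise ValueError(f"unknown split {kind!r}")
        coded = (v > t).astype(float).where(v.notna())
    nz = coded.dropna()
    if nz.nunique() < 2:
        raise ValueError("split yields an empty class")
    return PhenotypeVector(coded, trait_name, "binary", "binarized")


# ---------------------------------------------------------------------------

def _blup_adjust(y: np.ndarray, varieties: np.ndarray, env: np.ndarray) -> pd.Series:
    """Random-variety alternative: shrunken variety BLUPs, two components.

    Small-data implementation by direct covariance construction and
    Nelder-Mead over the two log variance ratios.
    """
    from scipy.optimize import minimize

    var_levels, var_idx = np.unique(varieties, return_inverse=True)
    env_levels, env_idx = np.unique(env, return_inverse=True)
    n = len(y)
    Zv = np.zeros((n, len(var_levels)))
    Zv[np.arange(n), var_idx] = 1.0
    Ze = np.zeros((n, len(env_levels)))
    Ze[np.arange(n), env_idx] = 1.0
    X = np.ones((n, 1))
    Gv = Zv @ Zv.T
    Ge = Ze @ Ze.T

    def negll(theta):
        gv, ge = np.exp(theta)
        V = gv * Gv + ge * Ge + np.eye(n)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        Vi_r = np.linalg.solve(V, r)
        rss = float(r @ Vi_r)
        s2 = rss / (n - 1)
        logdetV = 2 * np.sum(np.log(np.diag(L)))
        _, logdetA = np.linalg.slogdet(XtViX)
        return 0.5 * ((n - 1) * np.log(s2) + logdetV + logdetA)

    res = minimize(negll, x0=np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400})
    gv, ge = np.exp(res.x)
    V = gv * Gv + ge * Ge + np.eye(n)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    r = y - X @ beta
    u = gv * (Zv.T @ np.linalg.solve(V, r))
    return pd.Series(float(beta[0]) + u, index=var_levels)


def adjust_env(records: TraitTable | pd.DataFrame, trait: str | None = None,
               method: str = "blue") -> PhenotypeVector:
    """Location-by-year adjusted per-variety phenotype.

    Fits value = mu + variety (fixed) + u_(location,year) (random, iid
    Gaussian) + residual by REML and returns the variety BLUEs.  With a
    single environment the model is unidentifiable and the raw per-variety
    values are returned unchanged.  ``method="blup"`` instead treats
    variety as random and returns shrunken predictions.
    """
    if isinstance(records, TraitTable):
        if trait is None:
            traits = records.df["trait"].unique()
            if len(traits) != 1:
                raise ValueError("specify which trait to adjust")
            trait = str(traits[0])
        df = records.trait(trait)
    else:
        df = records.copy()
        trait = trait or str(df["trait"].iloc[0])
    if len(df) < 2:
        raise ValueError("need >= 2 records to adjust")
    env = (df["location"].astype(str) + "|" + df["year"].astype(str)).to_numpy()
    y = df["value"].to_numpy(dtype=float)
    varieties = df["variety"].to_numpy()
    env_levels = np.unique(env)
    if len(env_levels) < 2:
        out = pd.Series(y, index=varieties).groupby(level=0).mean()
        return PhenotypeVector(out, trait, "quantitative", "env_adjusted")
    if method == "blup":
        out = _blup_adjust(y, varieties, env)
        return PhenotypeVector(out, trait, "quantitative", "env_adjusted")
    if method != "blue":
        raise ValueError(f"unknown adjustment method {method!r}")

    var_levels, var_idx = np.unique(varieties, return_inverse=True)
    n = len(y)
    X = np.zeros((n, len(var_levels)))          # cell-means coding: BLUE per variety
    X[np.arange(n), var_idx] = 1.0
    _, env_idx = np.unique(env, return_inverse=True)
    Ze = np.zeros((n, len(env_levels)))
    Ze[np.arange(n), env_idx] = 1.0
    K_env = Ze @ Ze.T                            # iid environment random effect
    if n <= X.shape[1] + 1:
        # one record per (variety, environment) cell with no replication:
        # fall back to per-variety means of env-centered values
        log.warning("adjust_env: too few records for REML; using env-centered means")
        env_mean = pd.Series(y).groupby(env).transform("mean").to_numpy()
        centered = y - env_mean + y.mean()
        out = pd.Series(centered, index=varieties).groupby(level=0).mean()
        return PhenotypeVector(out, trait, "quantitative", "env_adjusted")
    fit = reml_fit(y, X, K_env)
    out = pd.Series(fit.covariate_effects, index=var_levels)
    return PhenotypeVector(out, trait, "quantitative", "env_adjusted")


def standardize(vector: PhenotypeVector) -> PhenotypeVector:
    """Z-score a phenotype: mean 0, standard deviation 1 (idempotent).

    Standardized phenotypes make per-marker effect sizes directly
    comparable across traits; scan p-values are unchanged by this affine
    transformation.
    """
    v = vector.values.dropna()
    sd = float(v.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant phenotype")
    z = (vector.values - float(v.mean())) / sd
    return PhenotypeVector(z, vector.trait_name, "quantitative", "standardized")


def trait_correlations(table: TraitTable, traits: list[str] | None = None,
                       min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between per-variety trait means.

    Cells with fewer than ``min_pairs`` complete observation pairs are NaN.
    """
    traits = traits or sorted(table.df["trait"].unique())
    wide = (table.df[table.df["trait"].isin(traits)]
            .groupby(["variety", "trait"])["value"].mean()
            .unstack("trait")
            .reindex(columns=traits))
    corr = wide.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr
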