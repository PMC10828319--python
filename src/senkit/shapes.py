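"""Per-gene count-distribution fitting, KS screening and switching censuses.

Each gene at each timepoint is fit by maximum likelihood under four count
families — Poisson (P), zero-inflated Poisson (ZIP), negative binomial (NB)
and zero-inflated negative binomial (ZINB) — with a log link on the mean and
biological replicate as a categorical covariate (so the mean varies by
replicate while the zero-inflation probability ``pi`` and NB size ``theta``
are shared).  With a saturated replicate factor the per-replicate mean MLE
has a closed form (the replicate sample mean, weighted by the zero-atom
responsibilities for the inflated families), which the fitters exploit:

* P    — per-replicate sample means.
* NB   — profile likelihood: means are replicate sample means for any
         ``theta``; ``theta`` by 1-D Brent search on the log scale.
* ZIP  — EM on the zero-atom membership; both M-step updates closed form.
* ZINB — EM with the NB profile nested inside the M-step.

Goodness of fit is a Kolmogorov-Smirnov statistic against the fitted
replicate-mixture CDF with a parametric-bootstrap p-value (the model is
re-simulated under the fitted parameters and refit, so the p-value accounts
for parameter estimation).  The best family per gene/timepoint is the
minimum-BIC fit among those passing the KS screen; genes are then classified
by how their selected family switches across the three timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

FAMILIES = ("P", "ZIP", "NB", "ZINB")
_FAMILY_ORDER = {f: i for i, f in enumerate(FAMILIES)}
_LOG_THETA_BOUNDS = (-7.0, 16.0)
PI_COLLAPSE = 1e-4       # pi below this: refit as the non-inflated family
THETA_POISSON_LIMIT = 1e4  # theta above this: flag as Poisson limit
_EM_TOL = 1e-6
_EM_MAX_ITER = 200


# ---------------------------------------------------------------- pmf helpers

def _pois_logpmf(y, mu):
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(y > 0, y * np.log(mu), 0.0) - mu - gammaln(y + 1)
    return np.where((mu == 0) & (y > 0), -np.inf, out)


def _nb_logpmf(y, mu, theta):
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
               + theta * np.log(theta / (theta + mu))
               + np.where(y > 0, y * np.log(mu / (theta + mu)), 0.0))
    return np.where((mu == 0) & (y > 0), -np.inf, out)


# -------------------------------------------------------------------- results

@dataclass
class ShapeFit:
    """One family's maximum-likelihood fit for one gene at one timepoint."""

    gene: str
    timepoint: str
    family: str
    mu: np.ndarray                 # per-replicate fitted means
    rep_levels: np.ndarray         # replicate level names, aligned with mu
    theta: float | None
    pi: float | None
    loglik: float
    k: int
    n: int
    converged: bool
    poisson_limit: bool = False
    ks_d: float | None = None
    ks_p: float | None = None
    _rep_codes: np.ndarray | None = field(default=None, repr=False)

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2.0 * self.loglik

    @property
    def beta(self) -> np.ndarray:
        """Log-link coefficients: intercept plus replicate contrasts."""
        with np.errstate(divide="ignore"):
            logmu = np.log(self.mu)
        return np.concatenate([[logmu[0]], logmu[1:] - logmu[0]])


@dataclass
class ShapeAssignment:
    gene: str
    timepoint: str
    family: str | None             # None when no family passed the KS screen
    fits: dict = field(default_factory=dict)


# ------------------------------------------------------------------- fitting

def _encode(replicate_labels, n) -> tuple[np.ndarray, np.ndarray]:
    if replicate_labels is None:
        return np.zeros(n, dtype=np.intp), np.asarray(["R1"])
    codes, levels = pd.factorize(np.asarray(replicate_labels), sort=True)
    if len(codes) != n:
        raise ValueError("replicate_labels length mismatch")
    return codes.astype(np.intp), np.asarray(levels)


class _Suff:
    """Per-replicate sufficient statistics of a count vector.

    Counts are small integers, so every likelihood here depends on the data
    only through the per-replicate value histogram (``V``/``C``/``G``:
    unique values, their multiplicities, their replicate index), the zero
    counts ``nz``, the totals ``sy`` and the sizes ``n``.  Fitting on the
    compressed form makes the EM updates per-replicate scalar recursions
    and the theta profile a sum over histogram bins, which is what keeps the
    parametric bootstrap affordable.
    """

    __slots__ = ("n", "sy", "nz", "V", "C", "G", "Vp", "Cp", "Gp", "R",
                 "total")

    def __init__(self, y: np.ndarray, codes: np.ndarray, R: int):
        self.R = R
        self.n = np.bincount(codes, minlength=R).astype(float)
        self.sy = np.bincount(codes, weights=y, minlength=R)
        self.nz = np.bincount(codes[y == 0], minlength=R).astype(float)
        Vs, Cs, Gs = [], [], []
        for r in range(R):
            v, c = np.unique(y[codes == r], return_counts=True)
            Vs.append(v)
            Cs.append(c.astype(float))
            Gs.append(np.full(len(v), r, dtype=np.intp))
        self.V = np.concatenate(Vs)
        self.C = np.concatenate(Cs)
        self.G = np.concatenate(Gs)
        pos = self.V > 0
        self.Vp, self.Cp, self.Gp = self.V[pos], self.C[pos], self.G[pos]
        self.total = int(self.n.sum())


def _profile_theta(s: _Suff, mu: np.ndarray, wz: np.ndarray | None = None):
    """Maximize the NB log-likelihood over log(theta) by Brent search.

    ``wz`` (per-replicate zero-atom responsibilities) down-weights zeros for
    the ZINB M-step; None means plain NB.
    """
    mu_p = mu[s.Gp]

    def nll(lt):
        theta = np.exp(lt)
        ll = float(np.sum(s.Cp * _nb_logpmf(s.Vp, mu_p, theta)))
        with np.errstate(divide="ignore"):
            lp0 = theta * np.log(theta / (theta + mu))
        wzero = s.nz if wz is None else s.nz * (1.0 - wz)
        return -(ll + float(np.sum(wzero * lp0)))

    res = minimize_scalar(nll, bounds=_LOG_THETA_BOUNDS, method="bounded",
                          options={"xatol": 1e-5})
    return float(np.exp(res.x))


def _fit_poisson(s: _Suff):
    mu = np.where(s.n > 0, s.sy / np.maximum(s.n, 1.0), 0.0)
    ll = float(np.sum(s.C * _pois_logpmf(s.V, mu[s.G])))
    return mu, ll


def _fit_nb(s: _Suff):
    mu = np.where(s.n > 0, s.sy / np.maximum(s.n, 1.0), 0.0)
    theta = _profile_theta(s, mu)
    ll = float(np.sum(s.C * _nb_logpmf(s.V, mu[s.G], theta)))
    return mu, theta, ll


def _zip_loglik(s: _Suff, mu, pi):
    ll_zero = float(np.sum(s.nz * np.log(pi + (1 - pi) * np.exp(-mu))))
    ll_pos = float(np.sum(s.Cp * (np.log1p(-pi)
                                  + _pois_logpmf(s.Vp, mu[s.Gp]))))
    return ll_zero + ll_pos


def _fit_zip(s: _Suff):
    if s.nz.sum() == 0:
        mu, ll = _fit_poisson(s)
        return mu, 0.0, ll
    mu = np.maximum(s.sy / np.maximum(s.n, 1.0), 1e-8)
    pi = 0.5 * s.nz.sum() / s.total
    ll_old = -np.inf
    for _ in range(_EM_MAX_ITER):
        wz = pi / (pi + (1 - pi) * np.exp(-mu) + 1e-300)  # per replicate
        pi = min(float(np.sum(s.nz * wz)) / s.total, 1 - 1e-10)
        den = s.n - s.nz * wz
        mu = np.maximum(np.where(den > 1e-12, s.sy / np.maximum(den, 1e-12),
                                 0.0), 1e-10)
        if pi < PI_COLLAPSE:
            break
        ll = _zip_loglik(s, mu, pi)
        if abs(ll - ll_old) < _EM_TOL:
            break
        ll_old = ll
    if pi < PI_COLLAPSE:
        mu, ll = _fit_poisson(s)
        return mu, 0.0, ll
    return mu, float(pi), ll


def _zinb_loglik(s: _Suff, mu, theta, pi):
    with np.errstate(divide="ignore"):
        nb0 = np.exp(theta * np.log(theta / (theta + mu)))
    ll_zero = float(np.sum(s.nz * np.log(pi + (1 - pi) * nb0)))
    ll_pos = float(np.sum(s.Cp * (np.log1p(-pi)
                                  + _nb_logpmf(s.Vp, mu[s.Gp], theta))))
    return ll_zero + ll_pos


def _fit_zinb(s: _Suff):
    if s.nz.sum() == 0:
        mu, theta, ll = _fit_nb(s)
        return mu, theta, 0.0, ll
    mu, theta, _ = _fit_nb(s)
    mu = np.maximum(mu, 1e-8)
    pi = 0.5 * s.nz.sum() / s.total
    wz = np.zeros(s.R)
    ll_outer = -np.inf
    ll = -np.inf
    for _outer in range(40):
        # inner EM on (pi, mu) with theta fixed: per-replicate scalar updates
        for _ in range(_EM_MAX_ITER):
            nb0 = np.exp(theta * np.log(theta / (theta + mu)))
            wz = pi / (pi + (1 - pi) * nb0 + 1e-300)
            pi_new = min(float(np.sum(s.nz * wz)) / s.total, 1 - 1e-10)
            den = s.n - s.nz * wz
            mu_new = np.maximum(
                np.where(den > 1e-12, s.sy / np.maximum(den, 1e-12), 0.0),
                1e-10)
            delta = abs(pi_new - pi) + float(np.max(np.abs(mu_new - mu)
                                                    / (1.0 + mu)))
            pi, mu = pi_new, mu_new
            if delta < 1e-9 or pi < PI_COLLAPSE:
                break
        if pi < PI_COLLAPSE:
            break
        theta = _profile_theta(s, mu, wz=wz)
        ll = _zinb_loglik(s, mu, theta, pi)
        if abs(ll - ll_outer) < _EM_TOL:
            break
        ll_outer = ll
    if pi < PI_COLLAPSE:
        mu, theta, ll = _fit_nb(s)
        return mu, theta, 0.0, ll
    return mu, float(theta), float(pi), ll


def fit_family(y, replicate_labels=None, family: str = "P",
               gene: str = "", timepoint: str = "") -> ShapeFit:
    """Maximum-likelihood fit of one count family with replicate covariate.

    Counts must be non-negative integers.  All-zero input is degenerate for
    every family (the rate / the zero-inflation sit on the parameter-space
    boundary) and is returned flagged non-converged.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty count vector")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    y = np.round(y).astype(np.int64)
    codes, levels = _encode(replicate_labels, y.size)
    R = len(levels)
    k = R + {"P": 0, "ZIP": 1, "NB": 1, "ZINB": 2}[family]

    base = dict(gene=gene, timepoint=timepoint, family=family,
                rep_levels=levels, k=k, n=int(y.size))
    if not np.any(y > 0):
        return ShapeFit(mu=np.zeros(R), theta=None, pi=None, loglik=-np.inf,
                        converged=False, _rep_codes=codes, **base)

    s = _Suff(y, codes, R)
    theta = pi = None
    if family == "P":
        mu, ll = _fit_poisson(s)
    elif family == "NB":
        mu, theta, ll = _fit_nb(s)
    elif family == "ZIP":
        mu, pi, ll = _fit_zip(s)
    else:
        mu, theta, pi, ll = _fit_zinb(s)

    converged = np.isfinite(ll)
    poisson_limit = theta is not None and theta > THETA_POISSON_LIMIT
    return ShapeFit(mu=np.asarray(mu, dtype=float), theta=theta, pi=pi,
                    loglik=ll, converged=bool(converged),
                    poisson_limit=poisson_limit, _rep_codes=codes, **base)


# ----------------------------------------------------------- goodness of fit

def _model_cdf(fit: ShapeFit, xs: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Fitted marginal CDF over the pooled replicates (replicate mixture)."""
    n = len(codes)
    weights = np.bincount(codes, minlength=len(fit.mu)) / n
    cdf = np.zeros_like(xs, dtype=float)
    for r, w in enumerate(weights):
        if w == 0:
            continue
        mu_r = fit.mu[r]
        if mu_r <= 0:
            base = np.ones_like(xs, dtype=float)
        elif fit.family in ("P", "ZIP"):
            base = poisson.cdf(xs, mu_r)
        else:
            base = nbinom.cdf(xs, fit.theta, fit.theta / (fit.theta + mu_r))
        if fit.family in ("ZIP", "ZINB"):
            base = fit.pi + (1 - fit.pi) * base
        cdf += w * base
    return cdf


def ks_statistic(fit: ShapeFit, y: np.ndarray, codes: np.ndarray) -> float:
    """D = sup over the count support of |empirical CDF - fitted CDF|."""
    y = np.asarray(y, dtype=np.int64)
    xs = np.arange(int(y.max()) + 1)
    ecdf = np.cumsum(np.bincount(y, minlength=len(xs))) / y.size
    return float(np.max(np.abs(ecdf - _model_cdf(fit, xs, codes))))


def _simulate_from_fit(fit: ShapeFit, codes: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    mu = fit.mu[codes]
    if fit.family in ("P", "ZIP"):
        y = rng.poisson(mu)
    else:
        theta = fit.theta
        y = np.where(mu > 0,
                     rng.negative_binomial(theta,
                                           theta / (theta + np.maximum(mu, 1e-12))),
                     0)
    if fit.family in ("ZIP", "ZINB"):
        y = np.where(rng.random(len(y)) < fit.pi, 0, y)
    return y.astype(np.int64)


def ks_gof(fit: ShapeFit, y, n_boot: int = 100,
           seed: int | np.random.Generator = 0) -> float:
    """Parametric-bootstrap KS p-value for a converged fit.

    Bootstrap replicates are simulated under the fitted parameters with the
    observed replicate design, refit under the same family, and their KS
    statistics compared with the observed one:
    ``p = (1 + #{D_b >= D_obs}) / (n_boot + 1)``.
    """
    if not fit.converged:
        raise ValueError("ks_gof requires a converged fit")
    if n_boot < 19:
        raise ValueError("n_boot must be >= 19 for usable p-value resolution")
    y = np.asarray(y, dtype=np.int64)
    codes = fit._rep_codes
    rep_labels = fit.rep_levels[codes]
    d_obs = ks_statistic(fit, y, codes)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        yb = _simulate_from_fit(fit, codes, rng)
        fb = fit_family(yb, rep_labels, fit.family,
                        gene=fit.gene, timepoint=fit.timepoint)
        if not fb.converged:
            exceed += 1  # degenerate resample counts against the null
            continue
        if ks_statistic(fb, yb, codes) >= d_obs:
            exceed += 1
    p = (1 + exceed) / (n_boot + 1)
    fit.ks_d, fit.ks_p = d_obs, p
    return p


# ------------------------------------------------------------------ selection

def assign_shape(y, replicate_labels=None, alpha: float = 0.05,
                 n_boot: int = 100, seed: int = 0,
                 gene: str = "", timepoint: str = "") -> ShapeAssignment:
    """Select the best-fitting family for one gene at one timepoint.

    All four families are fit; fits that fail to converge or fail the KS
    screen at ``alpha`` are discarded; among the survivors the minimum-BIC
    fit wins, with ties broken toward fewer parameters (P, then ZIP/NB,
    then ZINB).  If nothing survives the family is None.

    The KS bootstrap is evaluated lazily in ascending-BIC order: as soon as
    a family passes, every remaining (worse-BIC) family is dominated and
    need not be screened — the selected family is identical to screening
    all four first.
    """
    fits = {}
    for fam in FAMILIES:
        fits[fam] = fit_family(y, replicate_labels, fam, gene=gene,
                               timepoint=timepoint)
    ranked = sorted((f for f in fits.values() if f.converged),
                    key=lambda f: (f.bic, f.k, _FAMILY_ORDER[f.family]))
    best = None
    for fit in ranked:
        p = ks_gof(fit, y, n_boot=n_boot,
                   seed=np.random.default_rng([seed,
                                               _FAMILY_ORDER[fit.family]]))
        if p >= alpha:
            best = fit
            break
    if best is None:
        return ShapeAssignment(gene, timepoint, None, fits)
    return ShapeAssignment(gene, timepoint, best.family, fits)


def assign_shapes(adata, alpha: float = 0.05, n_boot: int = 100,
                  seed: int = 0, timepoint_col: str = "timepoint",
                  replicate_col: str = "replicate") -> pd.DataFrame:
    """Run assign_shape for every gene at every timepoint of a count matrix.

    Returns a tidy frame (gene, timepoint, family, bic, ks_p, converged
    families) — the raw material for the shape and switch censuses.
    """
    import scipy.sparse as sp
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    rows = []
    timepoints = pd.unique(adata.obs[timepoint_col])
    for t_idx, tp in enumerate(timepoints):
        mask = (adata.obs[timepoint_col] == tp).to_numpy()
        reps = adata.obs.loc[mask, replicate_col].to_numpy() \
            if replicate_col in adata.obs else None
        for g_idx, gene in enumerate(adata.var_names):
            a = assign_shape(X[mask, g_idx], reps, alpha=alpha,
                             n_boot=n_boot,
                             seed=int(np.random.default_rng(
                                 [seed, t_idx, g_idx]).integers(2 ** 31)),
                             gene=gene, timepoint=str(tp))
            best = a.fits.get(a.family) if a.family else None
            rows.append({"gene": gene, "timepoint": str(tp),
                         "family": a.family if a.family else "NONE",
                         "bic": best.bic if best else np.nan,
                         "ks_p": best.ks_p if best else np.nan})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ switching

SWITCH_CATEGORIES = ("stable", "single_transition", "reverting",
                     "distinct_triple", "unassigned")


def classify_switch(a0, a1, a2) -> str:
    """Classify a gene's family triple across the three timepoints.

    unassigned: any timepoint unassigned; stable: same family throughout;
    single_transition: exactly one consecutive change; reverting: A-B-A;
    distinct_triple: three different families.  "Differentially distributed"
    genes are the reverting plus distinct_triple categories — the patterns
    that change at both consecutive transitions.
    """
    triple = []
    for a in (a0, a1, a2):
        if a is None or a == "NONE":
            return "unassigned"
        if a not in FAMILIES:
            raise ValueError(f"unknown family {a!r}")
        triple.append(a)
    a0, a1, a2 = triple
    if a0 == a1 == a2:
        return "stable"
    if (a0 == a1) != (a1 == a2):  # exactly one consecutive change
        return "single_transition"
    if a0 == a2:
        return "reverting"
    return "distinct_triple"


@dataclass
class SwitchRecord:
    gene: str
    triple: tuple
    category: str


def make_switch_records(assignments: pd.DataFrame,
                        timepoints: Sequence[str] = ("T0", "T1", "T2"),
                        ) -> list[SwitchRecord]:
    """Build per-gene switch records from a tidy assignment frame."""
    wide = assignments.pivot(index="gene", columns="timepoint",
                             values="family")
    records = []
    for gene, row in wide.iterrows():
        triple = tuple(row.get(tp, "NONE") for tp in timepoints)
        records.append(SwitchRecord(gene, triple, classify_switch(*triple)))
    return records


def shape_census(assignments, denominator: int | None = None) -> pd.DataFrame:
    """Per-timepoint family counts and percentages among KS-passing genes.

    ``denominator`` fixes the percentage base (e.g. the total number of
    KS-passing genes); when None each timepoint uses its own count of
    assigned (non-NONE) genes.
    """
    if isinstance(assignments, pd.DataFrame):
        df = assignments[["gene", "timepoint", "family"]].copy()
    else:
        df = pd.DataFrame([{"gene": a.gene, "timepoint": a.timepoint,
                            "family": a.family if a.family else "NONE"}
                           for a in assignments])
    if df.duplicated(["gene", "timepoint"]).any():
        raise ValueError("duplicate (gene, timepoint) assignment")
    df = df[df["family"] != "NONE"]
    rows = []
    for tp, sub in df.groupby("timepoint", sort=True):
        denom = denominator if denominator is not None else len(sub)
        counts = sub["family"].value_counts()
        for fam in FAMILIES:
            c = int(counts.get(fam, 0))
            rows.append({"timepoint": tp, "family": fam, "count": c,
                         "pct": 100.0 * c / denom if denom else np.nan})
    return pd.DataFrame(rows)


def switch_census(records: Sequence[SwitchRecord],
                  denominator: int | None = None,
                  ) -> tuple[pd.DataFrame, dict]:
    """Per-pattern counts and block totals of distribution switching.

    Returns a pattern table (triple, category, count) plus a totals dict:
    the distinct-triple block total, the reverting block total, their sum
    (the "differentially distributed" genes), and percentages relative to
    ``denominator`` (the KS-passing gene count) when supplied.
    """
    seen = set()
    for r in records:
        if r.gene in seen:
            raise ValueError(f"duplicate record for gene {r.gene}")
        seen.add(r.gene)
    df = pd.DataFrame([{"t0": r.triple[0], "t1": r.triple[1],
                        "t2": r.triple[2], "category": r.category}
                       for r in records])
    if df.empty:
        patterns = pd.DataFrame(columns=["t0", "t1", "t2", "category",
                                         "count"])
        totals = {c: 0 for c in SWITCH_CATEGORIES}
        totals["differentially_distributed"] = 0
        return patterns, totals
    patterns = (df.groupby(["t0", "t1", "t2", "category"])
                .size().reset_index(name="count")
                .sort_values(["category", "count"],
                             ascending=[True, False], ignore_index=True))
    totals = {c: int((df["category"] == c).sum()) for c in SWITCH_CATEGORIES}
    dd = totals["reverting"] + totals["distinct_triple"]
    totals["differentially_distributed"] = dd
    if denominator:
        totals["pct_differential_of_denominator"] = 100.0 * dd / denominator
    if dd:
        totals["pct_all_three_of_differential"] = \
            100.0 * totals["distinct_triple"] / dd
    return patterns, totals
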