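"""Screening, rescaling, and two-block hierarchical logistic regression.

The analysis pipeline mirrors standard practice for a binary outcome with a
small predictor set:

1.  Belsley collinearity diagnostics on the unit-length-scaled design matrix
    (condition indexes from the singular values; variance-decomposition
    proportions; a dimension is flagged when its condition index exceeds 30
    and two or more variables load > 0.5 on it).
2.  Box-Tidwell-style linearity-of-the-logit check: one logistic model with
    every predictor plus its x * ln(x) interaction; each interaction's Wald
    p-value is reported and linearity passes when all exceed 0.05.
3.  z-score outlier screen on the predictor columns with a strict |z| > 3.29
    cutoff, and removal of successful-network cases that registered no
    passes.
4.  Rescaling of the three [0, 1] network metrics to a 0..10 scale so that
    each reported odds ratio refers to a 0.1 change of the raw metric.
5.  A two-block fit: block 1 enters total passes only; block 2 adds the
    three network metrics.  Each block reports the likelihood-ratio
    improvement G over the constant-only model, and block 2 additionally its
    improvement over block 1, so the metrics' effect is estimated after
    controlling for pass volume.

The logistic fits are maximum likelihood via iteratively reweighted least
squares (Newton-Raphson on the log-likelihood), with standard errors from the
inverse observed information, Wald chi-square statistics (beta/se)^2 against
chi2(1), odds ratios exp(beta) with normal-theory 95% intervals, Nagelkerke's
pseudo-R^2, the Hosmer-Lemeshow decile-of-risk goodness-of-fit test
(df = groups - 2), and a 0.5-cutoff classification table.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

METRIC_COLS = ("density", "clustering", "centralization")
RESCALED_FLAG = "metrics_rescaled"


class SeparationError(RuntimeError):
    """The likelihood is maximized at infinity (quasi-)separated data."""


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


@dataclass
class ScreeningReport:
    condition_indexes: np.ndarray
    variance_proportions: pd.DataFrame  # dimensions x variables
    collinearity_flags: list[tuple[int, list[str]]]
    logit_linearity_p: dict[str, float] = field(default_factory=dict)
    outlier_ids: list = field(default_factory=list)
    zero_pass_ids: list = field(default_factory=list)

    @property
    def collinearity_detected(self) -> bool:
        return bool(self.collinearity_flags)

    @property
    def logit_linear(self) -> bool:
        return all(p > 0.05 for p in self.logit_linearity_p.values())


def _design(cases: pd.DataFrame, terms: Sequence[str], add_constant: bool = True) -> tuple[np.ndarray, list[str]]:
    cols = list(terms)
    X = cases.loc[:, cols].to_numpy(dtype=float)
    names = cols
    if add_constant:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["constant"] + cols
    return X, names


def screen_collinearity(cases: pd.DataFrame, predictors: Sequence[str]) -> ScreeningReport:
    """Belsley condition-index / variance-proportion collinearity diagnostics.

    The design (intercept column included) is column-scaled to unit Euclidean
    length; condition indexes are the ratios of the largest singular value to
    each singular value, and the variance-decomposition proportion of
    variable j on dimension k is (v_jk / s_k)^2 normalized over k.  A
    dimension is flagged when its index exceeds 30 and at least two variables
    have proportions above 0.5 there.  An exactly rank-deficient design
    yields an infinite condition index and flags every variable loading on
    the null dimension.
    """
    if len(cases) < len(predictors) + 2:
        raise ValueError("need at least p + 2 cases for collinearity diagnostics")
    X, names = _design(cases, predictors)
    norms = np.linalg.norm(X, axis=0)
    if (norms == 0).any():
        raise ValueError("zero-variance column in design (cannot scale to unit length)")
    Xs = X / norms
    _, s, vt = np.linalg.svd(Xs, full_matrices=False)
    with np.errstate(divide="ignore"):
        cond = s.max() / s
    # variance decomposition: phi_jk = v_jk^2 / s_k^2, proportions over k
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (vt.T**2) / (s**2)  # variables x dimensions
    phi = np.where(np.isfinite(phi), phi, np.inf)
    props = np.zeros_like(phi)
    for j in range(phi.shape[0]):
        row = phi[j]
        if np.isinf(row).any():
            props[j] = np.isinf(row).astype(float) / np.isinf(row).sum()
        else:
            props[j] = row / row.sum()
    prop_df = pd.DataFrame(props.T, columns=names)  # dimensions x variables
    flags: list[tuple[int, list[str]]] = []
    for k in range(len(s)):
        if cond[k] > 30 or not np.isfinite(cond[k]):
            loaded = [names[j] for j in range(len(names)) if props[j, k] > 0.5]
            if len(loaded) >= 2:
                flags.append((k, loaded))
    return ScreeningReport(
        condition_indexes=cond,
        variance_proportions=prop_df,
        collinearity_flags=flags,
    )


def test_logit_linearity(
    cases: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = "outcome",
    shift: str = "auto",
) -> dict[str, float]:
    """Wald p-values of the x * ln(x) interactions, all in a single block.

    ``ln`` is undefined at zero and the network metrics can be exactly zero,
    so when a predictor has nonpositive values it is shifted by +1 inside the
    interaction term (``shift="auto"``, the documented convention);
    ``shift="none"`` raises instead, naming the offending predictor.
    Linearity of the logit is considered met when every interaction p-value
    exceeds 0.05.
    """
    df = cases.copy()
    inter_terms = []
    for p in predictors:
        x = df[p].to_numpy(dtype=float)
        if (x <= 0).any():
            if shift == "none":
                raise ValueError(
                    f"predictor {p!r} has nonpositive values; ln(x) is undefined -- "
                    "use shift='auto' to apply the +1 offset convention"
                )
            xs = x + 1.0
        else:
            xs = x
        name = f"{p}_xlnx"
        df[name] = xs * np.log(xs)
        inter_terms.append(name)
    fit = fit_logistic(df, list(predictors) + inter_terms, outcome=outcome, on_separation="flag")
    return {p: fit.p[f"{p}_xlnx"] for p in predictors}


def screen_outliers(
    cases: pd.DataFrame, predictors: Sequence[str], threshold: float = 3.29
) -> list:
    """Index labels of cases with any predictor |z-score| strictly above threshold.

    z-scores use the sample mean and SD (ddof=1) of each predictor column; a
    zero-variance column contributes no outliers.
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 cases for z-scores")
    flagged = pd.Series(False, index=cases.index)
    for p in predictors:
        x = cases[p].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        z = (x - x.mean()) / sd
        flagged |= z.abs() > threshold
    return list(cases.index[flagged])


def drop_zero_pass_sop(cases: pd.DataFrame) -> pd.DataFrame:
    """Remove successful-network cases that registered no passes.

    Only successful (outcome = 1) zero-pass cases are dropped; zero-pass
    unsuccessful cases are retained.
    """
    mask = (cases["outcome"] == 1) & (cases["total_passes"] == 0)
    return cases.loc[~mask].copy()


def rescale_metrics(cases: pd.DataFrame, factor: float = 10.0) -> pd.DataFrame:
    """Convert the three [0, 1] metrics to a 0..factor scale (default 0..10).

    After rescaling, each odds ratio for a metric refers to a change of
    1/factor on the raw scale (0.1 by default).  ``total_passes`` is left
    untouched.  The returned frame is flagged and a second rescale of an
    already-rescaled frame is refused.
    """
    if cases.attrs.get(RESCALED_FLAG):
        raise ValueError("metrics already rescaled; refusing to rescale twice")
    out = cases.copy()
    for c in METRIC_COLS:
        if c in out.columns:
            out[c] = out[c].astype(float) * factor
    out.attrs = dict(cases.attrs)
    out.attrs[RESCALED_FLAG] = True
    return out


# ---------------------------------------------------------------------------
# the logistic engine
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """A fitted binary logistic model and its SPSS-style report quantities."""

    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    wald: dict[str, float]
    p: dict[str, float]
    odds_ratio: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    loglik: float
    loglik_null: float
    n: int
    fitted: np.ndarray
    y: np.ndarray
    block: int | None = None
    converged: bool = True
    separation: bool = False
    g_vs_null: float | None = None
    g_vs_null_df: int | None = None
    g_vs_null_p: float | None = None
    g_vs_previous: float | None = None
    g_vs_previous_df: int | None = None
    g_vs_previous_p: float | None = None

    def summary_rows(self) -> list[dict]:
        rows = []
        order = [t for t in self.terms if t != "constant"] + (
            ["constant"] if "constant" in self.terms else []
        )
        for t in order:
            rows.append(
                {
                    "term": t,
                    "beta": self.coef[t],
                    "se": self.se[t],
                    "wald": self.wald[t],
                    "p": self.p[t],
                    "exp_beta": self.odds_ratio[t],
                    "ci_low": self.ci95[t][0],
                    "ci_high": self.ci95[t][1],
                }
            )
        return rows


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood with logit link
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    cases: pd.DataFrame,
    terms: Sequence[str],
    outcome: str = "outcome",
    *,
    on_separation: str = "raise",
    max_iter: int = 100,
    tol_score: float = 1e-8,
    tol_ll: float = 1e-10,
) -> ModelFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    An intercept ("constant") is always included.  Convergence is declared
    when the largest score component falls below ``tol_score`` or the
    relative log-likelihood change falls below ``tol_ll``, within
    ``max_iter`` Newton steps.  Standard errors come from the inverse
    observed information; Wald chi-squares (beta/se)^2 are referred to
    chi2(1); odds-ratio intervals are exp(beta +/- 1.96 se).

    (Quasi-)separation is detected as a standardized coefficient exceeding 15
    in absolute value and is reported -- raised as :class:`SeparationError`
    by default, or flagged on the returned fit with ``on_separation="flag"``.
    """
    y = cases[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    X, names = _design(cases, terms)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more cases ({n}) than model terms ({k})")

    beta = np.zeros(k)
    ll = _loglik(y, X @ beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol_score:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        beta_new = beta + step
        ll_new = _loglik(y, X @ beta_new)
        # step-halving keeps Newton monotone on awkward starts
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 20:
            step *= 0.5
            beta_new = beta + step
            ll_new = _loglik(y, X @ beta_new)
            halvings += 1
        ll_old = ll
        beta, ll = beta_new, ll_new
        if abs(ll - ll_old) <= tol_ll * (abs(ll_old) + 1e-300):
            converged = True
            break
    eta = X @ beta
    p_hat = expit(eta)

    # separation check on the standardized scale
    scale = np.ones(k)
    for j in range(k):
        if names[j] != "constant":
            sd = X[:, j].std(ddof=1)
            scale[j] = sd if sd > 0 else 1.0
    separated = bool(np.any(np.abs(beta * scale) > 15.0))
    if separated and on_separation == "raise":
        raise SeparationError(
            "quasi-separation detected: a standardized coefficient exceeds 15 "
            "(the maximum-likelihood estimate diverges)"
        )

    w = np.clip(p_hat * (1.0 - p_hat), 1e-12, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diagonal(cov), 0.0, None))

    # constant-only reference fit (closed form: intercept = logit of the mean)
    ybar = y.mean()
    if 0.0 < ybar < 1.0:
        b0 = math.log(ybar / (1.0 - ybar))
        ll0 = _loglik(y, np.full(n, b0))
    else:
        ll0 = 0.0

    coef = dict(zip(names, beta))
    se_d = dict(zip(names, se))
    wald = {t: (coef[t] / se_d[t]) ** 2 if se_d[t] > 0 else math.inf for t in names}
    pvals = {t: float(stats.chi2.sf(wald[t], df=1)) for t in names}
    _exp = lambda v: float(np.exp(np.clip(v, -745.0, 709.0)))  # overflow-safe on separated fits
    ors = {t: _exp(coef[t]) for t in names}
    cis = {
        t: (_exp(coef[t] - 1.96 * se_d[t]), _exp(coef[t] + 1.96 * se_d[t]))
        for t in names
    }
    return ModelFit(
        terms=names,
        coef=coef,
        se=se_d,
        wald=wald,
        p=pvals,
        odds_ratio=ors,
        ci95=cis,
        loglik=ll,
        loglik_null=ll0,
        n=n,
        fitted=p_hat,
        y=y,
        converged=converged,
        separation=separated,
    )


@dataclass
class HierarchicalFit:
    block1: ModelFit
    block2: ModelFit


def hierarchical_fit(
    cases: pd.DataFrame,
    block1_terms: Sequence[str] = ("total_passes",),
    block2_terms: Sequence[str] = METRIC_COLS,
    outcome: str = "outcome",
    **kwargs,
) -> HierarchicalFit:
    """Two-block fit: block 1 alone, then block 1 + block 2.

    Each block reports G = -2 (LL_reduced - LL_full) against the
    constant-only model; block 2 additionally reports its improvement over
    block 1, the likelihood-ratio test of the added terms after controlling
    for the block-1 predictors.  G statistics are additive:
    G(null -> block 2) = G(null -> block 1) + G(block 1 -> block 2).
    """
    fit1 = fit_logistic(cases, list(block1_terms), outcome=outcome, **kwargs)
    fit2 = fit_logistic(cases, list(block1_terms) + list(block2_terms), outcome=outcome, **kwargs)
    for fit, df_null in ((fit1, len(block1_terms)), (fit2, len(block1_terms) + len(block2_terms))):
        g = -2.0 * (fit.loglik_null - fit.loglik)
        fit.g_vs_null = g
        fit.g_vs_null_df = df_null
        fit.g_vs_null_p = float(stats.chi2.sf(g, df=df_null))
    g12 = -2.0 * (fit1.loglik - fit2.loglik)
    fit2.g_vs_previous = g12
    fit2.g_vs_previous_df = len(block2_terms)
    fit2.g_vs_previous_p = float(stats.chi2.sf(g12, df=len(block2_terms)))
    fit1.block, fit2.block = 1, 2
    return HierarchicalFit(block1=fit1, block2=fit2)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def hosmer_lemeshow(fit: ModelFit, groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow decile-of-risk goodness-of-fit test.

    Cases are cut into ``groups`` equal-count bins of the fitted
    probabilities (quantile cutpoints, ties kept together, so fewer distinct
    fitted values yield fewer bins); chi2 sums (O - E)^2 / E over both
    outcome columns of every bin; df = bins - 2.  A bin whose expected
    success or failure count is zero is merged with its neighbor, reducing
    df, with a warning.
    """
    p = np.asarray(fit.fitted, dtype=float)
    y = np.asarray(fit.y, dtype=float)
    try:
        bins = pd.qcut(p, q=groups, duplicates="drop")
        codes = bins.codes
    except ValueError:
        codes = np.zeros(len(p), dtype=int)
    frame = pd.DataFrame({"p": p, "y": y, "bin": codes})
    g = frame.groupby("bin", observed=True).agg(n=("y", "size"), o1=("y", "sum"), e1=("p", "sum"))
    g = g.sort_index()
    rows = [(int(r.n), float(r.o1), float(r.e1)) for r in g.itertuples()]
    # merge bins with a zero expected count into their neighbor
    merged = []
    for row in rows:
        if merged and (row[2] <= 0 or (row[0] - row[2]) <= 0):
            n0, o0, e0 = merged[-1]
            merged[-1] = (n0 + row[0], o0 + row[1], e0 + row[2])
            warnings.warn("Hosmer-Lemeshow: merged a bin with zero expected count")
        else:
            merged.append(list(row))
    rows = merged
    if len(rows) >= 2 and (rows[0][2] <= 0 or (rows[0][0] - rows[0][2]) <= 0):
        n0, o0, e0 = rows.pop(0)
        rows[0] = [rows[0][0] + n0, rows[0][1] + o0, rows[0][2] + e0]
        warnings.warn("Hosmer-Lemeshow: merged a bin with zero expected count")
    chi2 = 0.0
    for n_g, o1, e1 in rows:
        e0 = n_g - e1
        o0 = n_g - o1
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = max(len(rows) - 2, 1)
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df=df))


def nagelkerke_r2(fit: ModelFit) -> float:
    """Nagelkerke pseudo-R^2: Cox-Snell rescaled to a [0, 1] maximum."""
    n = fit.n
    r2_cs = 1.0 - math.exp(2.0 * (fit.loglik_null - fit.loglik) / n)
    max_cs = 1.0 - math.exp(2.0 * fit.loglik_null / n)
    if max_cs <= 0:
        return 0.0
    return float(min(max(r2_cs / max_cs, 0.0), 1.0))


def classification_table(fit: ModelFit, cutoff: float = 0.5) -> dict:
    """2x2 classification at the given probability cutoff plus percentages.

    Predicts success when the fitted probability is >= cutoff; reports the
    percentage of unsuccessful and of successful cases correctly classified,
    and the overall percentage correct.
    """
    pred = (fit.fitted >= cutoff).astype(int)
    y = fit.y.astype(int)
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tp = int(((pred == 1) & (y == 1)).sum())
    n0, n1 = tn + fp, fn + tp
    return {
        "table": {"tn": tn, "fp": fp, "fn": fn, "tp": tp},
        "pct_uop_correct": 100.0 * tn / n0 if n0 else float("nan"),
        "pct_sop_correct": 100.0 * tp / n1 if n1 else float("nan"),
        "pct_overall_correct": 100.0 * (tn + tp) / (n0 + n1),
        "cutoff": cutoff,
    }


# ---------------------------------------------------------------------------
# odds-ratio helpers and reporting
# ---------------------------------------------------------------------------


def odds_ratio(beta: float) -> float:
    """Exp(beta): multiplicative change in success odds per unit predictor change."""
    return math.exp(beta)


def odds_ratio_ci(beta: float, se: float, z: float = 1.96) -> tuple[float, float]:
    """Normal-theory 95% interval for exp(beta)."""
    return math.exp(beta - z * se), math.exp(beta + z * se)


def odds_percent_change(or_value: float) -> float:
    """Odds ratio restated as a percentage change in the odds.

    An odds ratio above 1 is reported as the percentage increase
    (100 (OR - 1)); one below 1 as the percentage decrease (100 (1 - OR)),
    i.e. how much a unit increase of the predictor shrinks the odds -- or,
    equivalently, how much a unit decrease raises them.
    """
    if or_value >= 1.0:
        return 100.0 * (or_value - 1.0)
    return 100.0 * (1.0 - or_value)


_TERM_LABELS = {
    "total_passes": "Total number of passes",
    "density": "Density scores",
    "clustering": "Clustering coefficient scores",
    "centralization": "Centralization scores",
    "constant": "Constant",
}


def _fit_payload(fit: ModelFit) -> dict:
    hl_chi2, hl_df, hl_p = hosmer_lemeshow(fit)
    cls = classification_table(fit)
    return {
        "block": fit.block,
        "n": fit.n,
        "terms": fit.summary_rows(),
        "loglik": fit.loglik,
        "loglik_null": fit.loglik_null,
        "G_vs_null": fit.g_vs_null,
        "G_vs_null_df": fit.g_vs_null_df,
        "G_vs_null_p": fit.g_vs_null_p,
        "G_vs_previous": fit.g_vs_previous,
        "G_vs_previous_df": fit.g_vs_previous_df,
        "G_vs_previous_p": fit.g_vs_previous_p,
        "nagelkerke_r2": nagelkerke_r2(fit),
        "hosmer_lemeshow": {"chi2": hl_chi2, "df": hl_df, "p": hl_p},
        "classification": cls,
    }


def model_report(screen: ScreeningReport | None, fits: HierarchicalFit) -> dict:
    """Machine-readable report of the full analysis (JSON-serializable dict).

    Use :func:`render_report` for the human-readable coefficient table with
    columns beta (S.E.), Wald, p, Exp(beta) and its 95% interval.
    """
    report: dict = {"blocks": [_fit_payload(fits.block1), _fit_payload(fits.block2)]}
    if screen is not None:
        report["screening"] = {
            "condition_indexes": [float(c) for c in screen.condition_indexes],
            "collinearity_flags": [
                {"dimension": int(d), "variables": vs} for d, vs in screen.collinearity_flags
            ],
            "logit_linearity_p": {k: float(v) for k, v in screen.logit_linearity_p.items()},
            "logit_linear": screen.logit_linear,
            "outlier_ids": [str(i) for i in screen.outlier_ids],
            "zero_pass_ids": [str(i) for i in screen.zero_pass_ids],
        }
    return report


def render_report(report: dict) -> str:
    """Plain-text render of the final block's coefficient table and diagnostics."""
    lines = []
    for blk in report["blocks"]:
        lines.append(f"Block {blk['block']} (n = {blk['n']})")
        lines.append(
            f"{'':32s} {'b (S.E.)':>16s} {'Wald':>8s} {'p':>7s} {'Exp(b)':>8s} "
            f"{'95% CI low':>10s} {'95% CI high':>11s}"
        )
        for row in blk["terms"]:
            label = _TERM_LABELS.get(row["term"], row["term"])
            ci = "" if row["term"] == "constant" else f"{row['ci_low']:>10.3f} {row['ci_high']:>11.3f}"
            lines.append(
                f"{label:32s} {row['beta']:8.3f} ({row['se']:.3f}) {row['wald']:8.3f} "
                f"{row['p']:7.3f} {row['exp_beta']:8.3f} {ci}"
            )
        g = blk["G_vs_null"]
        lines.append(
            f"  G vs constant-only = {g:.3f} (df {blk['G_vs_null_df']}, p = {blk['G_vs_null_p']:.3f})"
        )
        if blk["G_vs_previous"] is not None:
            lines.append(
                f"  G vs previous block = {blk['G_vs_previous']:.3f} "
                f"(df {blk['G_vs_previous_df']}, p = {blk['G_vs_previous_p']:.3f})"
            )
        hl = blk["hosmer_lemeshow"]
        lines.append(
            f"  Hosmer-Lemeshow chi2({hl['df']}) = {hl['chi2']:.3f}, p = {hl['p']:.3f}; "
            f"Nagelkerke r2 = {blk['nagelkerke_r2']:.3f}"
        )
        cls = blk["classification"]
        lines.append(
            f"  Classified correctly: UOP {cls['pct_uop_correct']:.1f}%, "
            f"SOP {cls['pct_sop_correct']:.1f}%, overall {cls['pct_overall_correct']:.1f}%"
        )
        lines.append("")
    return "\n".join(lines)


def run_analysis(
    cases: pd.DataFrame,
    *,
    z_threshold: float = 3.29,
    rescale_factor: float = 10.0,
    hl_groups: int = 10,
    cutoff: float = 0.5,
) -> tuple[ScreeningReport, HierarchicalFit, pd.DataFrame]:
    """The full screening + two-block pipeline on a NetworkCase table.

    Returns the screening report, the hierarchical fit on the screened and
    rescaled cases, and the analysis frame itself.  Screening order: drop
    zero-pass successful networks, z-score outlier removal, collinearity and
    linearity checks (reported, not acted on), metric rescaling to 0..10.
    """
    predictors = ["total_passes", *METRIC_COLS]
    kept = drop_zero_pass_sop(cases)
    zero_ids = [i for i in cases.index if i not in kept.index]
    outliers = screen_outliers(kept, predictors, threshold=z_threshold)
    kept = kept.drop(index=outliers)
    screen = screen_collinearity(kept, predictors)
    screen.outlier_ids = outliers
    screen.zero_pass_ids = zero_ids
    scaled = rescale_metrics(kept, factor=rescale_factor)
    screen.logit_linearity_p = test_logit_linearity(scaled, predictors)
    fits = hierarchical_fit(scaled)
    # attach requested diagnostics settings
    for fit in (fits.block1, fits.block2):
        fit.hl_groups = hl_groups  # type: ignore[attr-defined]
        fit.cutoff = cutoff  # type: ignore[attr-defined]
    return screen, fits, scaled


def report_to_json(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=float)
        fh.write("\n")
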