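"""Nucleation scores with calibrated errors.

For variant *i* in replicate *r* the enrichment score is
``ES_i = ln F_i(output) - ln F_i(input)`` over within-sample frequencies
``F``, and the nucleation score is ``NS_i = ES_i - ES_wt`` — the log
enrichment relative to wild type, so WT scores exactly 0 by construction.

Measurement error is modelled from the Poisson noise floor of count data:

    sigma^2_{i,r} = m_in[r]  * (v_in,i,r  + v_in,wt,r)
                  + m_out[r] * (v_out,i,r + v_out,wt,r) + a[r]

where ``v`` is the Poisson sampling variance of the log-count estimator
(~= 1/count, evaluated exactly at low counts), with replicate-specific
multiplicative modifiers ``m_in, m_out >= 1`` (count overdispersion in the
input and output samples) and an additive term ``a >= 0`` (variant-level
noise not explained by counting). The modifiers are fit over all variants
at once by iteratively reweighted least squares on the leverage-corrected
squared replicate residuals, whose expectations are linear in the
modifiers. Replicates are merged
by the error-weighted mean and scores centered so synonymous variants
arising from single nucleotide changes average zero. Effect classes are
assigned by a z-test with Benjamini-Hochberg FDR control.

Two numerical refinements keep the estimator calibrated down to the low
output counts of strongly depleted variants: the plug-in log is debiased
with the exact Poisson expectation of ``ln(C + pseudocount)`` at the
variant's pooled expected count, and variance terms / merging weights are
computed from pooled expected counts rather than per-replicate observed
counts (observed-count weights correlate with the noise they weigh and
attenuate the merged scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .variant_calling import input_columns, output_columns

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class ErrorModel:
    """Fitted per-replicate variance modifiers."""

    m_in: np.ndarray  # multiplicative, input Poisson term, >= 1
    m_out: np.ndarray  # multiplicative, output Poisson term, >= 1
    a: np.ndarray  # additive variance, >= 0
    replicates: list[int] = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.m_in = np.atleast_1d(np.asarray(self.m_in, dtype=float))
        self.m_out = np.atleast_1d(np.asarray(self.m_out, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if not self.replicates:
            self.replicates = list(range(1, len(self.m_in) + 1))

    def variance(self, in_term: np.ndarray, out_term: np.ndarray) -> np.ndarray:
        """Modelled NS variance given per-replicate Poisson terms (variants x reps)."""
        return in_term * self.m_in + out_term * self.m_out + self.a

    def to_dict(self) -> dict:
        return {
            "replicates": list(self.replicates),
            "m_in": self.m_in.tolist(),
            "m_out": self.m_out.tolist(),
            "a": self.a.tolist(),
            "converged": bool(self.converged),
        }


def _replicate_numbers(table: pd.DataFrame) -> list[int]:
    reps_in = {int(c[len("input"):]) for c in input_columns(table)}
    reps_out = {int(c[len("output"):]) for c in output_columns(table)}
    if reps_in != reps_out:
        raise ValueError("input and output replicate sets differ")
    return sorted(reps_in)


def _wt_index(table: pd.DataFrame) -> int:
    wt = np.flatnonzero(table["n_nt_subs"].to_numpy() == 0)
    if len(wt) == 0:
        raise ValueError("no_wildtype: count table has no n_nt_subs == 0 row")
    return int(wt[0])


def _count_arrays(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[int]]:
    reps = _replicate_numbers(table)
    cin = table[[f"input{r}" for r in reps]].to_numpy(float)
    cout = table[[f"output{r}" for r in reps]].to_numpy(float)
    return cin, cout, reps


# ---------------------------------------------------------------------------
# Exact Poisson moments of the log-count estimator


def poisson_log_moments(
    lam: np.ndarray, pseudocount: float, exact_below: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """Bias and variance of ``ln(C + pseudocount)`` for C ~ Poisson(lam).

    Below ``exact_below`` the moments are computed by the exact Poisson
    sum; above it the bias is negligible and the variance is the familiar
    1/lam delta-method floor. lam == 0 (variant unseen in a sample) gets
    bias 0 — nothing can be corrected there — and the variance of the
    smallest observable count.
    """
    lam = np.asarray(lam, float)
    bias = np.zeros_like(lam)
    var = np.empty_like(lam)
    high = lam >= exact_below
    var[high] = 1.0 / np.maximum(lam[high], 1.0)
    low = ~high
    if low.any():
        l = np.maximum(lam[low], 1e-8)[:, None]
        c = np.arange(0, int(exact_below * 4 + 20))[None, :]
        pmf = stats.poisson.pmf(c, l)
        logs = np.log(c + pseudocount)
        e1 = (pmf * logs).sum(axis=1)
        e2 = (pmf * logs ** 2).sum(axis=1)
        bias_low = e1 - np.log(np.maximum(lam[low], 1e-8))
        bias_low[lam[low] <= 1e-12] = 0.0
        bias[low] = bias_low
        var[low] = np.maximum(e2 - e1 ** 2, 1e-12)
    return bias, var


def pooled_expected_counts(counts: np.ndarray) -> np.ndarray:
    """Expected per-replicate counts from replicate-pooled frequencies.

    Each variant's frequency is estimated on the pooled counts and scaled
    by every replicate's depth, denoising the per-replicate count estimate
    that enters variance terms and weights.
    """
    totals = counts.sum(axis=0)
    freq = counts.sum(axis=1) / counts.sum()
    return freq[:, None] * totals[None, :]


def compute_enrichment(
    table: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    bias_correction: bool = False,
) -> pd.DataFrame:
    """Per-replicate nucleation scores NS_i = ES_i - ES_wt (natural log).

    Frequencies use ``(count + pseudocount) / sum(count + pseudocount)``;
    the normalising totals cancel between variant and WT, so NS is
    invariant to sequencing depth when the pseudocount is 0. With
    ``bias_correction`` the exact Poisson bias of the plug-in log is
    subtracted, evaluated at each variant's pooled expected count.
    """
    cin, cout, reps = _count_arrays(table)
    wt = _wt_index(table)
    if pseudocount <= 0 and (np.any(cin <= 0) or np.any(cout <= 0)):
        raise ValueError("zero counts present; use a positive pseudocount")
    lin = pooled_expected_counts(cin) if bias_correction else None
    lout = pooled_expected_counts(cout) if bias_correction else None
    ns = {}
    for j, r in enumerate(reps):
        log_in = np.log(cin[:, j] + pseudocount)
        log_out = np.log(cout[:, j] + pseudocount)
        if bias_correction:
            log_in -= poisson_log_moments(lin[:, j], pseudocount)[0]
            log_out -= poisson_log_moments(lout[:, j], pseudocount)[0]
        # within-sample totals cancel in ES_i - ES_wt, so they are omitted
        es = log_out - log_in
        ns[f"ns_rep{r}"] = es - es[wt]
    return pd.DataFrame(ns, index=table.index)


def poisson_terms(
    table: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    pooled: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant, per-replicate Poisson variance floors v_i + v_wt.

    With ``pooled`` (default) the variance of the log-count estimator is
    evaluated at pooled expected counts; otherwise at the observed counts
    plus pseudocount (the naive plug-in).
    """
    cin, cout, reps = _count_arrays(table)
    wt = _wt_index(table)
    if pooled:
        # 1/(lambda + pc): the delta-method variance of ln(C + pc) with the
        # pseudocount as regulariser. The exact low-lambda variance of the
        # estimator is smaller, but lambda-hat itself is then so uncertain
        # that the regularised form reflects the real error better.
        vin = 1.0 / (pooled_expected_counts(cin) + pseudocount)
        vout = 1.0 / (pooled_expected_counts(cout) + pseudocount)
    else:
        vin = 1.0 / (cin + pseudocount)
        vout = 1.0 / (cout + pseudocount)
    in_term = vin + vin[wt][None, :]
    out_term = vout + vout[wt][None, :]
    return in_term, out_term


def fit_error_model(
    table: pd.DataFrame,
    ns_rep: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_iter: int = 100,
    tol: float = 1e-6,
    df_correction: bool = True,
    pooled: bool = True,
    min_fit_count: float = 10.0,
) -> ErrorModel:
    """Fit the replicate-specific variance modifiers.

    Uses iteratively reweighted least squares on the moment conditions of
    the normal model: given current variances, each leverage-corrected
    squared residual ``(ns_{i,r} - mu_i)^2 / (1 - w_{i,r}/sum_r w_{i,r})``
    (``mu_i`` the precision-weighted replicate mean) has expectation
    ``sigma^2_{i,r}``, which is linear in the modifiers; a bounded weighted
    least-squares step (weights 1/sigma^4, the inverse residual variance
    under normality) updates the modifiers per replicate, and the loop
    repeats to convergence. The leverage correction undoes the
    degrees-of-freedom loss from estimating ``mu_i`` on the same
    replicates; without it fitted variances are biased low by ~ (R-1)/R.

    Variants whose pooled expected count falls below ``min_fit_count`` in
    any sample are excluded from the fit (their counts sit against the
    zero floor, so their replicate scatter is censored and no longer
    reflects the modelled variance); the fitted model is still applied to
    every variant.
    """
    reps = _replicate_numbers(table)
    n_rep = len(reps)
    if n_rep < 2:
        raise ValueError("error model requires at least two replicates")
    in_term, out_term = poisson_terms(table, pseudocount, pooled=pooled)
    y = ns_rep[[f"ns_rep{r}" for r in reps]].to_numpy(float)
    cin, cout, _ = _count_arrays(table)
    expected = np.hstack([pooled_expected_counts(cin), pooled_expected_counts(cout)])
    informative = (expected >= min_fit_count).all(axis=1)
    if informative.sum() >= 50:  # keep everything on tiny toy tables
        y = y[informative]
        in_term = in_term[informative]
        out_term = out_term[informative]

    theta = np.concatenate([np.ones(2 * n_rep), np.full(n_rep, 1e-3)])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        var = in_term * theta[:n_rep] + out_term * theta[n_rep: 2 * n_rep] + theta[2 * n_rep:]
        w = 1.0 / var
        mu = (y * w).sum(axis=1) / w.sum(axis=1)
        resid2 = (y - mu[:, None]) ** 2
        if df_correction:
            leverage = w / w.sum(axis=1, keepdims=True)
            resid2 = resid2 / np.maximum(1.0 - leverage, 1e-3)
        new = np.empty_like(theta)
        for j in range(n_rep):
            design = np.column_stack(
                [in_term[:, j], out_term[:, j], np.ones(len(y))]
            )
            sqw = 1.0 / var[:, j]  # sqrt of the 1/sigma^4 WLS weight
            res = optimize.lsq_linear(
                design * sqw[:, None],
                resid2[:, j] * sqw,
                bounds=([1.0, 1.0, 0.0], [np.inf, np.inf, np.inf]),
            )
            new[j], new[n_rep + j], new[2 * n_rep + j] = res.x
        if np.allclose(new, theta, rtol=tol, atol=tol):
            theta = new
            converged = True
            break
        theta = new
    if not converged:
        import warnings

        warnings.warn("error-model fit did not converge; returning last iterate")
    return ErrorModel(
        m_in=theta[:n_rep], m_out=theta[n_rep: 2 * n_rep], a=theta[2 * n_rep:],
        replicates=reps, converged=converged, n_iterations=it,
    )


def replicate_variances(
    table: pd.DataFrame,
    model: ErrorModel,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    pooled: bool = True,
) -> pd.DataFrame:
    in_term, out_term = poisson_terms(table, pseudocount, pooled=pooled)
    var = model.variance(in_term, out_term)
    return pd.DataFrame(
        {f"var_rep{r}": var[:, j] for j, r in enumerate(model.replicates)},
        index=table.index,
    )


def merge_replicates(ns_rep: pd.DataFrame, var_rep: pd.DataFrame) -> pd.DataFrame:
    """Error-weighted mean across replicates; merged variance is 1/sum(1/sigma^2)."""
    y = ns_rep.to_numpy(float)
    w = 1.0 / var_rep.to_numpy(float)
    wsum = w.sum(axis=1)
    return pd.DataFrame(
        {"ns": (y * w).sum(axis=1) / wsum, "sigma": 1.0 / np.sqrt(wsum)},
        index=ns_rep.index,
    )


def center_scores(scores: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Center NS on the error-weighted mean of single-nucleotide synonymous variants.

    Synonymous variants are true neutrals, so after centering their weighted
    mean is exactly zero; sigmas are unchanged. Returns the centered table
    and the offset that was subtracted.
    """
    mask = (scores["var_class"] == "synonymous") & (scores["n_nt_subs"] == 1)
    if not mask.any():
        raise ValueError("no_synonymous: no single-nt synonymous variants to center on")
    w = 1.0 / scores.loc[mask, "sigma"].to_numpy(float) ** 2
    offset = float(np.average(scores.loc[mask, "ns"].to_numpy(float), weights=w))
    out = scores.copy()
    out["ns"] = out["ns"] - offset
    return out, offset


def classify_effects(
    scores: pd.DataFrame, fdr: float = 0.1, two_sided: bool = True
) -> pd.DataFrame:
    """z-test against 0 with Benjamini-Hochberg FDR; classify each variant.

    ``increase``/``decrease`` when q < fdr with the corresponding sign of NS,
    else ``wt_like``. The BH correction runs over all scored variants.
    """
    out = scores.copy()
    z = out["ns"].to_numpy(float) / out["sigma"].to_numpy(float)
    if two_sided:
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        p = stats.norm.sf(np.abs(z))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out["z"] = z
    out["p"] = p
    out["q"] = q
    cls = np.where(q < fdr, np.where(out["ns"] > 0, "increase", "decrease"), "wt_like")
    cls[(q < fdr) & (out["ns"].to_numpy() == 0.0)] = "wt_like"
    out["effect_class"] = cls
    return out


def score_counts(
    table: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fdr: float = 0.1,
    min_input_reads: int = 50,
    max_aa_subs: int = 2,
    apply_filters: bool = True,
    bias_correction: bool = True,
    pooled: bool = True,
) -> tuple[pd.DataFrame, ErrorModel]:
    """Full scoring pipeline: filter, enrich, fit errors, merge, center, classify.

    Returns the score table (annotation columns, per-replicate scores and
    sigmas, merged ns/sigma, z, q, effect_class) and the fitted error model.
    """
    from .variant_calling import apply_variant_filters

    if apply_filters:
        table, _ = apply_variant_filters(
            table, min_input_reads=min_input_reads, max_aa_subs=max_aa_subs
        )
    table = table.reset_index(drop=True)
    ns_rep = compute_enrichment(table, pseudocount, bias_correction=bias_correction)
    model = fit_error_model(table, ns_rep, pseudocount, pooled=pooled)
    var_rep = replicate_variances(table, model, pseudocount, pooled=pooled)
    merged = merge_replicates(ns_rep, var_rep)

    ann_cols = [c for c in table.columns if not c.startswith(("input", "output"))]
    scores = pd.concat(
        [
            table[ann_cols],
            ns_rep,
            np.sqrt(var_rep).rename(columns=lambda c: c.replace("var_", "sigma_")),
            merged,
        ],
        axis=1,
    )
    scores, _ = center_scores(scores)
    scores = classify_effects(scores, fdr=fdr)
    return scores, model
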