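"""Positional architecture: K-medoids clustering of residues, gatekeepers, regions.

Residue positions are clustered on their profiles of single amino-acid
mutant nucleation scores (a positions x mutant-aa matrix with missing
cells where a substitution was not scored). Partitioning around medoids
(PAM) is run for K in a range, the optimum chosen by average silhouette
width, and the stability of that choice assessed by resampling every cell
from its error distribution. Gatekeeper positions — where mutations are at
least as likely to increase as to decrease nucleation — are called from
per-position counts of significant effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .variant_calling import parse_aa_subs

AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# Position matrix


def build_position_matrix(
    scores: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positions x mutant-aa matrices of merged NS and sigma for single-aa missense.

    Several nucleotide variants encoding the same amino-acid substitution
    are combined by the error-weighted mean; nonsense (stop) variants never
    populate the matrix. Missing substitutions stay NaN.
    """
    singles = scores[(scores["var_class"] == "missense") & (scores["n_aa_subs"] == 1)]
    n_pos = len(scores.loc[scores["n_nt_subs"] == 0, "aa_seq"].iloc[0]) if (scores["n_nt_subs"] == 0).any() else int(
        max(parse_aa_subs(t)[0][0] for t in singles["aa_subs"])
    )
    positions = pd.RangeIndex(1, n_pos + 1, name="position")
    ns_mat = pd.DataFrame(np.nan, index=positions, columns=AA_ORDER)
    sig_mat = pd.DataFrame(np.nan, index=positions, columns=AA_ORDER)

    groups: dict[tuple[int, str], list[tuple[float, float]]] = {}
    for row in singles.itertuples(index=False):
        (pos, _wt, mut), = parse_aa_subs(row.aa_subs)
        groups.setdefault((pos, mut), []).append((row.ns, row.sigma))
    for (pos, mut), vals in groups.items():
        ns = np.array([v[0] for v in vals])
        w = 1.0 / np.array([v[1] for v in vals]) ** 2
        ns_mat.loc[pos, mut] = np.average(ns, weights=w)
        sig_mat.loc[pos, mut] = 1.0 / np.sqrt(w.sum())
    return ns_mat, sig_mat


def position_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise distances between position rows tolerating missing cells.

    Euclidean over the columns observed in both rows, rescaled by
    sqrt(n_columns_total / n_shared) so sparsity does not shrink distances;
    reduces to plain Euclidean when nothing is missing.
    """
    x = matrix.to_numpy(float)
    n, p = x.shape
    obs = ~np.isnan(x)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[i] & obs[j]
            k = int(shared.sum())
            if k == 0:
                raise ValueError(f"disconnected: rows {i} and {j} share no observed columns")
            diff = x[i, shared] - x[j, shared]
            d[i, j] = d[j, i] = np.sqrt((diff ** 2).sum() * (p / k))
    return d


# ---------------------------------------------------------------------------
# PAM


def kmedoids(dist: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids (BUILD + SWAP) on a precomputed distance matrix.

    Deterministic: ties break toward the lowest index. Returns (medoid
    indices, assignment of each object to a medoid index).
    """
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    # BUILD: greedy cost minimisation
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        best_cand, best_cost = None, np.inf
        current = dist[:, medoids].min(axis=1)
        for c in range(n):
            if c in medoids:
                continue
            cost = np.minimum(current, dist[:, c]).sum()
            if cost < best_cost - 1e-12:
                best_cost, best_cand = cost, c
        medoids.append(best_cand)
    medoids = sorted(medoids)
    # SWAP: steepest descent
    while True:
        cost = dist[:, medoids].min(axis=1).sum()
        best_swap, best_cost = None, cost
        for mi, m in enumerate(medoids):
            for c in range(n):
                if c in medoids:
                    continue
                trial = medoids[:mi] + [c] + medoids[mi + 1:]
                tc = dist[:, trial].min(axis=1).sum()
                if tc < best_cost - 1e-12:
                    best_cost, best_swap = tc, (mi, c)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        medoids = sorted(medoids)
    medoid_arr = np.array(medoids)
    assign = medoid_arr[np.argmin(dist[:, medoid_arr], axis=1)]
    return medoid_arr, assign


def silhouette_select_k(
    dist: np.ndarray, k_range: tuple[int, int] = (1, 10)
) -> tuple[int, dict[int, float]]:
    """Average silhouette width for each K; returns (argmax K, widths).

    K=1 is assigned width 0 by convention, so K>=2 is chosen only when its
    clustering is better than no clustering at all. Ties go to the smaller K.
    """
    n = dist.shape[0]
    widths: dict[int, float] = {}
    for k in range(k_range[0], min(k_range[1], n - 1) + 1):
        if k == 1:
            widths[1] = 0.0
            continue
        _, assign = kmedoids(dist, k)
        if len(np.unique(assign)) < 2:
            widths[k] = 0.0
            continue
        width = silhouette_score(dist, assign, metric="precomputed")
        widths[k] = float(np.nan_to_num(width))  # identical rows -> 0/0 -> 0
    best = max(widths, key=lambda k: (widths[k], -k))
    return best, widths


def resample_cluster_stability(
    matrix: pd.DataFrame,
    sigmas: pd.DataFrame,
    n_draws: int = 100,
    k_range: tuple[int, int] = (1, 10),
    seed: int | np.random.Generator = 0,
) -> dict:
    """Assess clustering stability under score uncertainty.

    Each draw perturbs every observed cell by Normal(0, sigma_cell),
    recomputes the silhouette-optimal K and the partition, and accumulates
    the K distribution plus how often each pair of positions co-clusters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = matrix.to_numpy(float)
    s = sigmas.to_numpy(float)
    obs = ~np.isnan(x)
    n = x.shape[0]
    k_counts: dict[int, int] = {}
    co = np.zeros((n, n))
    for _ in range(n_draws):
        noise = np.where(obs, rng.normal(0.0, 1.0, size=x.shape) * np.where(obs, s, 0.0), 0.0)
        perturbed = pd.DataFrame(x + noise, index=matrix.index, columns=matrix.columns)
        dist = position_distance_matrix(perturbed)
        k, _ = silhouette_select_k(dist, k_range)
        k_counts[k] = k_counts.get(k, 0) + 1
        _, assign = kmedoids(dist, k)
        co += assign[:, None] == assign[None, :]
    co /= n_draws
    modal_k = max(k_counts, key=lambda k: (k_counts[k], -k))
    return {
        "modal_K": modal_k,
        "K_counts": dict(sorted(k_counts.items())),
        "co_cluster": pd.DataFrame(co, index=matrix.index, columns=matrix.index),
    }


# ---------------------------------------------------------------------------
# Position profiles, gatekeepers, regions


def position_profiles(scores: pd.DataFrame, fdr: float = 0.1) -> pd.DataFrame:
    """Per-position counts of significant single-aa effects at the stated FDR.

    Counts are over single amino-acid missense variants; when several
    nucleotide variants encode the same substitution each contributes once
    via the substitution-level matrix classification.
    """
    from .scoring import classify_effects

    ns_mat, sig_mat = build_position_matrix(scores)
    cells = ns_mat.stack().rename("ns").to_frame()
    cells["sigma"] = sig_mat.stack()
    cells = classify_effects(cells.reset_index(), fdr=fdr)
    prof = []
    for pos in ns_mat.index:
        sub = cells[cells["position"] == pos]
        n_up = int((sub["effect_class"] == "increase").sum())
        n_down = int((sub["effect_class"] == "decrease").sum())
        prof.append(
            {
                "position": int(pos),
                "n_up": n_up,
                "n_down": n_down,
                "n_wt_like": int((sub["effect_class"] == "wt_like").sum()),
                "n_observed": len(sub),
            }
        )
    return pd.DataFrame(prof)


def identify_gatekeepers(
    profiles: pd.DataFrame, min_signif_fraction: float = 0.5
) -> list[int]:
    """Positions where significant increases are at least as common as decreases.

    A position qualifies when n_up >= n_down and the significant fraction
    (n_up + n_down) / n_observed reaches ``min_signif_fraction`` — i.e. most
    of its mutations are significantly different from wild type.
    """
    out = []
    for row in profiles.itertuples(index=False):
        if row.n_observed == 0:
            continue
        signif = row.n_up + row.n_down
        if row.n_up >= row.n_down and signif > 0 and signif / row.n_observed >= min_signif_fraction:
            out.append(int(row.position))
    return sorted(out)


@dataclass
class RegionScheme:
    """Mutually exclusive position classes: Nt/Ct ranges plus gatekeeper set."""

    nt_range: tuple[int, int] = (2, 26)
    ct_range: tuple[int, int] = (27, 41)
    gatekeepers: tuple[int, ...] = ()

    def label(self, position: int) -> str:
        if position in self.gatekeepers:
            return "gatekeeper"
        if self.nt_range[0] <= position <= self.nt_range[1]:
            return "Nt"
        if self.ct_range[0] <= position <= self.ct_range[1]:
            return "Ct"
        return "unassigned"


def region_summary(
    scores: pd.DataFrame, scheme: RegionScheme, fdr: float | None = None
) -> pd.DataFrame:
    """Fractions of increase/decrease/wt_like per region, singles and doubles apart.

    A single counts toward the region containing its substituted position; a
    double only when BOTH substitutions fall in the same region class.
    Fractions are over variants observed in the region and sum to 1.
    """
    from .scoring import classify_effects

    if fdr is not None:
        scores = classify_effects(scores, fdr=fdr)
    rows = []
    missense = scores[scores["var_class"] == "missense"]
    for n_subs, kind in ((1, "single"), (2, "double")):
        sub = missense[missense["n_aa_subs"] == n_subs]
        labels = []
        for token in sub["aa_subs"]:
            labs = {scheme.label(p) for p, _, _ in parse_aa_subs(token)}
            labels.append(labs.pop() if len(labs) == 1 else "mixed")
        sub = sub.assign(region=labels)
        for region in ("Nt", "Ct", "gatekeeper"):
            grp = sub[sub["region"] == region]
            n = len(grp)
            if n == 0:
                continue
            counts = grp["effect_class"].value_counts()
            rows.append(
                {
                    "region": region,
                    "mutant_type": kind,
                    "n": n,
                    "frac_increase": counts.get("increase", 0) / n,
                    "frac_decrease": counts.get("decrease", 0) / n,
                    "frac_wt_like": counts.get("wt_like", 0) / n,
                }
            )
    return pd.DataFrame(rows)
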