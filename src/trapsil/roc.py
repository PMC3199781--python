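"""Nested case-control ROC-area enrichment and group comparison statistics.

Each case site (an integration site, or a gene-group TSS) is paired with its
own random matched controls.  For a feature quantified at every site and
control, the ROC area is the mean over sites of

    b_i + t_i / 2

where ``b_i`` is the fraction of site *i*'s controls whose feature value is
strictly below the site's value and ``t_i`` the fraction tied with it.  The
area lives in [0, 1]: 1 means the feature is enriched at case sites relative
to their matched controls, 0 means depleted, 0.5 means no difference.
Half-weighting ties is forced by requiring area(all ties) = 0.5 together
with case/control antisymmetry (swapping roles maps the area to 1 - area).

Group contrasts are tested two ways and both are reported: a likelihood-
ratio chi-square from conditional (matched-set) logistic regression with a
group x feature interaction, and a label-permutation test on the difference
of group ROC areas.  The permutation test exploits that each site's score
``b_i + t_i/2`` is computed against its own controls only, hence invariant
under group relabelling.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

MSEI_SITE = "TTAA"


@dataclass
class ControlSet:
    """Matched random controls for one case site."""

    site_id: str
    controls: list[tuple[str, int, str]]
    matching: str = "uniform"


# ---------------------------------------------------------------------------
# Matched controls
# ---------------------------------------------------------------------------

def _ttaa_positions(seq: str) -> np.ndarray:
    out, start = [], seq.find(MSEI_SITE)
    while start != -1:
        out.append(start)
        start = seq.find(MSEI_SITE, start + 1)
    return np.array(out, dtype=np.int64)


def matched_controls(
    sites: pd.DataFrame,
    sequences: dict[str, str],
    n_controls: int = 10,
    mode: str = "uniform",
    seed: int = 0,
    msei_tolerance: int = 100,
    max_tries: int = 200,
) -> dict[str, ControlSet]:
    """Draw ``n_controls`` random genomic positions per mapped site.

    ``uniform`` samples chromosomes proportionally to length and positions
    uniformly within them, with a random strand.  ``msei_matched``
    additionally matches each control's distance to the nearest MseI site
    (TTAA) to the case site's own distance within ``msei_tolerance`` bp — a
    surrogate for LM-PCR recoverability; chromosomes without any TTAA fall
    back to uniform with a warning.  Deterministic under ``seed``.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1 (ROC undefined without controls)")
    if mode not in ("uniform", "msei_matched"):
        raise ValueError(f"unknown control matching mode {mode!r}")
    rng = np.random.default_rng(seed)
    chroms = sorted(sequences)
    lengths = np.array([len(sequences[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    ttaa = {c: _ttaa_positions(sequences[c]) for c in chroms} if mode == "msei_matched" else {}
    from .features import distance_to_nearest  # local import avoids cycle

    out: dict[str, ControlSet] = {}
    mapped = sites[sites["status"] == "mapped"]
    for _, s in mapped.iterrows():
        site_id = s["read_id"]
        controls: list[tuple[str, int, str]] = []
        if mode == "msei_matched":
            own = ttaa.get(s["chrom"], np.array([]))
            target_d = distance_to_nearest(int(s["position"]), own) if own.size else math.nan
        for _ in range(n_controls):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            strand = "+" if rng.random() < 0.5 else "-"
            pos = int(rng.integers(0, len(sequences[chrom])))
            if mode == "msei_matched":
                pts = ttaa[chrom]
                if pts.size == 0 or math.isnan(target_d):
                    warnings.warn(f"no TTAA on {chrom}; uniform fallback for {site_id}")
                else:
                    best_pos, best_gap = pos, math.inf
                    for _try in range(max_tries):
                        cand = int(rng.integers(0, len(sequences[chrom])))
                        gap = abs(distance_to_nearest(cand, pts) - target_d)
                        if gap < best_gap:
                            best_pos, best_gap = cand, gap
                        if gap <= msei_tolerance:
                            break
                    pos = best_pos
            controls.append((chrom, pos, strand))
        out[site_id] = ControlSet(site_id, controls, mode)
    return out


# ---------------------------------------------------------------------------
# ROC area
# ---------------------------------------------------------------------------

def site_scores(case_values, control_values) -> np.ndarray:
    """Per-site score b_i + t_i/2 against the site's own controls.

    ``case_values``: length-n array; ``control_values``: list of n arrays
    (ragged allowed).  Sites with NaN case values, or with no non-NaN
    controls, yield NaN scores.
    """
    case_values = np.asarray(case_values, dtype=float)
    scores = np.full(len(case_values), np.nan)
    for i, (v, ctrls) in enumerate(zip(case_values, control_values)):
        ctrls = np.asarray(ctrls, dtype=float)
        ctrls = ctrls[~np.isnan(ctrls)]
        if math.isnan(v) or ctrls.size == 0:
            continue
        b = np.count_nonzero(ctrls < v)
        t = np.count_nonzero(ctrls == v)
        scores[i] = (b + t / 2) / ctrls.size
    return scores


def roc_area(case_values, control_values) -> float:
    """Matched-control ROC area: mean per-site score over usable sites.

    NaN-valued sites are dropped (their count is recoverable as the number
    of NaN entries of :func:`site_scores`).  Returns NaN when no site is
    usable.
    """
    scores = site_scores(case_values, control_values)
    usable = scores[~np.isnan(scores)]
    if usable.size == 0:
        return float("nan")
    n_dropped = len(scores) - usable.size
    if n_dropped:
        warnings.warn(f"roc_area: dropped {n_dropped} site(s) with NA values")
    return float(usable.mean())


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Heatmap matrix
# ---------------------------------------------------------------------------

def heatmap_matrix(
    site_groups: dict[str, pd.DataFrame],
    tracks: dict,
    scales,
    control_sets: dict[str, "ControlSet"],
    sequences: dict[str, str] | None = None,
    cutoff: float | None = 1,
) -> pd.DataFrame:
    """One ROC area per (site group, feature, interval scale).

    ``site_groups`` maps a group label to a table of mapped sites;
    ``control_sets`` must cover every site id.  An empty group yields NA
    rows.  Long-format output: group, feature, scale, area, n_sites.
    """
    from .features import IntervalScale, quantify

    scales = [s if isinstance(s, IntervalScale) else IntervalScale(int(s)) for s in scales]
    chrom_len = {c: len(s) for c, s in sequences.items()} if sequences else {}
    rows = []
    for glabel, gsites in site_groups.items():
        mapped = gsites[gsites["status"] == "mapped"] if "status" in gsites else gsites
        for fname, track in tracks.items():
            for scale in scales:
                if len(mapped) == 0:
                    rows.append(dict(group=glabel, feature=fname, scale=scale.label,
                                     area=np.nan, n_sites=0))
                    continue
                case_vals, ctrl_vals = [], []
                for _, s in mapped.iterrows():
                    cl = chrom_len.get(s["chrom"])
                    case_vals.append(
                        quantify(track, s["chrom"], int(s["position"]), scale,
                                 chrom_length=cl, cutoff=cutoff)
                    )
                    cs = control_sets[s["read_id"]]
                    ctrl_vals.append([
                        quantify(track, cc, int(cp), scale,
                                 chrom_length=chrom_len.get(cc), cutoff=cutoff)
                        for cc, cp, _cs in cs.controls
                    ])
                rows.append(dict(group=glabel, feature=fname, scale=scale.label,
                                 area=roc_area(case_vals, ctrl_vals),
                                 n_sites=len(mapped)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def _clogit_nll_grad(params, x, group, interaction):
    """Negative conditional-logistic log-likelihood and gradient.

    x: (n_sets, 1 + m) feature values, case in column 0; group: (n_sets,)
    0/1 indicator; eta = beta*x (+ gamma*x*group when interaction).  Each
    matched set contributes eta_case - log sum_j exp(eta_j).
    """
    beta = params[0]
    eta = beta * x
    if interaction:
        eta = eta + params[1] * x * group[:, None]
    lse = logsumexp(eta, axis=1)
    nll = float(-(eta[:, 0] - lse).sum())
    p = np.exp(eta - lse[:, None])          # within-set softmax
    resid = x[:, 0] - (p * x).sum(axis=1)   # case value minus expected value
    grad = [-resid.sum()]
    if interaction:
        grad.append(float(-(group * resid).sum()))
    return nll, np.array(grad)


def _fit_clogit(x, group, interaction):
    n_par = 2 if interaction else 1
    return optimize.minimize(
        _clogit_nll_grad, np.zeros(n_par), args=(x, group, interaction),
        method="BFGS", jac=True,
    )


def compare_groups(
    case_a, controls_a, case_b, controls_b,
    method: str = "both",
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Test whether a feature separates cases from matched controls
    differently in group A than in group B.

    ``chi2_clogit``: likelihood-ratio chi-square (df=1) for the group x
    feature interaction in a conditional logistic regression over matched
    sets; falls back to the permutation p (with a warning) when the fit
    separates completely or fails.  ``permutation``: two-sided p for the
    statistic |area_A - area_B| over random group-label reassignments of the
    per-site scores; exact enumeration when the total number of sites is
    small enough that all label assignments can be listed.

    Returns {"p_chi2": ..., "p_perm": ..., "area_a": ..., "area_b": ...}.
    """
    if method not in ("both", "chi2_clogit", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    sa = site_scores(case_a, controls_a)
    sb = site_scores(case_b, controls_b)
    sa, sb = sa[~np.isnan(sa)], sb[~np.isnan(sb)]
    if sa.size == 0 or sb.size == 0:
        raise ValueError("both groups need at least one usable site")
    out: dict[str, float] = {"area_a": float(sa.mean()), "area_b": float(sb.mean()),
                             "p_chi2": float("nan"), "p_perm": float("nan")}

    p_perm = None
    if method in ("both", "permutation") or method == "chi2_clogit":
        p_perm = _permutation_p(sa, sb, n_perm=n_perm, seed=seed)
    if method in ("both", "permutation"):
        out["p_perm"] = p_perm

    if method in ("both", "chi2_clogit"):
        xa = _stack_sets(case_a, controls_a)
        xb = _stack_sets(case_b, controls_b)
        if xa is None or xb is None or xa.shape[1] != xb.shape[1]:
            warnings.warn("clogit needs equal, rectangular control sets; using permutation p")
            out["p_chi2"] = p_perm
            return out
        x = np.vstack([xa, xb])
        # standardize for optimizer conditioning; LR is scale-invariant
        sd = x.std()
        if sd > 0:
            x = (x - x.mean()) / sd
        group = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
        full = _fit_clogit(x, group, interaction=True)
        red = _fit_clogit(x, group, interaction=False)
        ok = full.success and red.success and np.all(np.abs(full.x) < 30)
        if not ok:
            warnings.warn("clogit did not converge (possible separation); using permutation p")
            out["p_chi2"] = p_perm
        else:
            lr = max(0.0, 2 * (red.fun - full.fun))
            out["p_chi2"] = float(stats.chi2.sf(lr, df=1))
    return out


def _stack_sets(case_values, control_values) -> np.ndarray | None:
    case_values = np.asarray(case_values, dtype=float)
    sizes = {len(c) for c in control_values}
    if len(sizes) != 1:
        return None
    m = sizes.pop()
    x = np.empty((len(case_values), 1 + m))
    x[:, 0] = case_values
    for i, c in enumerate(control_values):
        x[i, 1:] = np.asarray(c, dtype=float)
    if np.isnan(x).any():
        return None
    return x


def _permutation_p(sa: np.ndarray, sb: np.ndarray, n_perm: int, seed: int) -> float:
    """Two-sided permutation p for |mean(sa) - mean(sb)| under group-label
    exchange; exact when the assignment count is below the Monte-Carlo
    budget, otherwise ``n_perm`` random draws with the +1 correction."""
    pooled = np.concatenate([sa, sb])
    na, n = len(sa), len(pooled)
    obs = abs(sa.mean() - sb.mean())
    total = math.comb(n, na)
    if total <= max(n_perm, 1):
        hits = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, na):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            if stat >= obs - 1e-12:
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed)
    # vectorized: one argsort of uniforms per permutation selects na labels
    hits = 0
    chunk = 2_000
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        u = rng.random((k, n))
        sel = np.argpartition(u, na - 1, axis=1)[:, :na]
        means_a = pooled[sel].mean(axis=1)
        sums = pooled.sum()
        means_b = (sums - means_a * na) / (n - na)
        hits += int(np.count_nonzero(np.abs(means_a - means_b) >= obs - 1e-12))
        done += k
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Expression comparison between gene groups
# ---------------------------------------------------------------------------

def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments
    of the pooled sample (handles ties, unlike the textbook null tables)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, nx = len(pooled), len(x)
    obs = abs(ranks[:nx].sum() - nx * (n + 1) / 2)
    hits = total = 0
    for comb in itertools.combinations(range(n), nx):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - nx * (n + 1) / 2) >= obs - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_expression(
    gene_groups: dict[str, np.ndarray | list], exact_max_n: int = 10
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of expression between gene
    groups.

    Exact enumeration when both groups have at most ``exact_max_n`` genes;
    otherwise the normal approximation with tie correction.  Empty groups
    give NA.
    """
    labels = list(gene_groups)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        x = np.asarray(gene_groups[a], dtype=float)
        y = np.asarray(gene_groups[b], dtype=float)
        if x.size == 0 or y.size == 0:
            p, method = float("nan"), "na"
        elif x.size <= exact_max_n and y.size <= exact_max_n:
            p, method = _exact_ranksum_p(x, y), "exact"
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="asymptotic").pvalue)
            method = "normal_approx"
        rows.append(dict(group_a=a, group_b=b, n_a=x.size, n_b=y.size,
                         p=p, method=method, stars=significance_stars(p)))
    return pd.DataFrame(rows)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted q-values, emitted alongside raw p-values for transparency
    (the headline stars use raw p-values)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
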