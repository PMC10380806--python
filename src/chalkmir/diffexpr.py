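"""Negative-binomial differential expression for miRNA count matrices.

Count model: y ~ NB(mu, phi) with var = mu + phi*mu^2 and a single common
dispersion estimated by conditional maximum likelihood on library-size
equalised pseudo-counts.  Two-group comparisons use a conditional exact
test on the group sums; the genotype x treatment interaction uses an NB
log-linear model with library-size offsets and a 1-df likelihood-ratio
test.  Raw p < 0.05 defines differential expression (a BH-adjusted column
is emitted for convenience but is not used for calls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "DEResult",
    "DispersionEstimate",
    "SetComparison",
    "estimate_common_dispersion",
    "exact_test_feature",
    "exact_test",
    "interaction_test",
    "compare_sets",
    "bh_adjust",
]

ALPHA = 0.05
PRIOR_COUNT = 0.5
_PHI_MIN = 1e-6
_PHI_MAX = 10.0


@dataclass
class DEResult:
    name: str
    contrast: str
    log2fc: float
    p_value: float
    direction: str  # up / down / ns


@dataclass
class DispersionEstimate:
    phi: float
    method: str = "conditional-ML"


def _pseudo_counts(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Rescale counts to the geometric-mean library size."""
    ref = np.exp(np.mean(np.log(lib_sizes)))
    return counts * (ref / lib_sizes)


def _cond_loglik(pseudo: np.ndarray, group_masks: list[np.ndarray], phi: float) -> float:
    """Conditional NB log-likelihood (terms free of phi dropped)."""
    r = 1.0 / phi
    total = 0.0
    for mask in group_masks:
        y = pseudo[:, mask]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) - y.size * gammaln(r)
            - np.sum(gammaln(z + n * r)) + len(z) * gammaln(n * r)
        )
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame | np.ndarray,
    groups: list[str] | np.ndarray,
    lib_sizes: pd.Series | np.ndarray,
) -> DispersionEstimate:
    """Common dispersion by conditional maximum likelihood.

    Library sizes are equalised by geometric-mean rescaling of the counts
    before conditioning on group sums.  The likelihood is maximised over
    log(phi) with a deterministic grid-then-refine search; groups need at
    least 2 libraries each to contribute.
    """
    counts = np.asarray(counts, dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    groups = np.asarray(groups)
    if counts.sum() == 0:
        warnings.warn("all-zero count matrix; dispersion set to 0", stacklevel=2)
        return DispersionEstimate(0.0)
    pseudo = _pseudo_counts(counts, lib_sizes)
    masks = []
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() >= 2:
            masks.append(mask)
    if not masks:
        raise ValueError("need at least one group with >= 2 libraries")
    # keep features with some signal; all-zero rows are uninformative
    keep = pseudo.sum(axis=1) > 0
    pseudo = pseudo[keep]

    def neg(log_phi: float) -> float:
        return -_cond_loglik(pseudo, masks, float(np.exp(log_phi)))

    grid = np.linspace(np.log(_PHI_MIN), np.log(_PHI_MAX), 40)
    values = np.array([neg(x) for x in grid])
    k = int(np.argmin(values))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    phi = float(np.exp(res.x))
    if neg(np.log(_PHI_MIN)) <= res.fun:  # boundary optimum: Poisson-like
        phi = _PHI_MIN
    return DispersionEstimate(phi)


def _conditional_sum_logpmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(S_A = a | S_A + S_B = t) for a = 0..t under equal means.

    Group sums of n iid NB(r, p) variables are NB(n*r, p); conditioning on
    the total cancels p.  phi = 0 degenerates to Binomial(t, n_a/(n_a+n_b)).
    """
    a = np.arange(t + 1)
    if phi <= 0:
        logw = (
            gammaln(t + 1) - gammaln(a + 1) - gammaln(t - a + 1)
            + a * np.log(n_a / (n_a + n_b))
            + (t - a) * np.log(n_b / (n_a + n_b))
        )
    else:
        r = 1.0 / phi
        logw = (
            gammaln(a + n_a * r) - gammaln(a + 1)
            + gammaln(t - a + n_b * r) - gammaln(t - a + 1)
        )
    logw = logw - logw.max()
    return logw - np.log(np.exp(logw).sum())


def exact_test_feature(
    y_a: np.ndarray,
    y_b: np.ndarray,
    phi: float,
    sizes_a: np.ndarray,
    sizes_b: np.ndarray,
    prior_count: float = PRIOR_COUNT,
) -> tuple[float, float]:
    """Conditional exact test for one feature; returns (log2fc, p).

    Counts are rescaled to the common (geometric-mean) library size and the
    group sums rounded; conditioned on the total, the two-sided p-value is
    the summed probability of all outcomes no more likely than the one
    observed.  log2fc is log2((mean_B + c) / (mean_A + c)) on the rescaled
    scale — positive means higher in group B.
    """
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    sizes = np.concatenate([np.asarray(sizes_a, float), np.asarray(sizes_b, float)])
    ref = np.exp(np.mean(np.log(sizes)))
    pa = y_a * (ref / np.asarray(sizes_a, float))
    pb = y_b * (ref / np.asarray(sizes_b, float))
    log2fc = float(np.log2((pb.mean() + prior_count) / (pa.mean() + prior_count)))

    s_a = int(round(pa.sum()))
    s_b = int(round(pb.sum()))
    t = s_a + s_b
    if t == 0:
        return 0.0, 1.0
    logp = _conditional_sum_logpmf(t, len(y_a), len(y_b), phi)
    p_obs = logp[s_a]
    p = float(np.exp(logp[logp <= p_obs + 1e-10]).sum())
    if p > 1.0 - 1e-9:  # whole distribution included; absorb fp summation error
        p = 1.0
    return log2fc, min(p, 1.0)


def _direction(log2fc: float, p: float, alpha: float = ALPHA) -> str:
    if p < alpha and log2fc > 0:
        return "up"
    if p < alpha and log2fc < 0:
        return "down"
    return "ns"


def exact_test(
    counts: pd.DataFrame,
    groups: list[str] | np.ndarray,
    group_a: str,
    group_b: str,
    phi: float,
    lib_sizes: pd.Series,
    contrast: str | None = None,
) -> pd.DataFrame:
    """Exact test for every feature; B-vs-A contrast (positive = up in B).

    Returns a DataFrame indexed by feature with columns log2fc, p_value,
    p_adj (Benjamini-Hochberg, informational) and direction at raw
    p < 0.05.
    """
    groups = np.asarray(groups)
    mask_a = groups == group_a
    mask_b = groups == group_b
    if mask_a.sum() < 1 or mask_b.sum() < 1:
        raise ValueError(f"empty group in contrast {group_b} vs {group_a}")
    sizes = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    mat = counts.to_numpy(dtype=float)
    label = contrast or f"{group_b}_vs_{group_a}"
    rows = []
    for i, name in enumerate(counts.index):
        lfc, p = exact_test_feature(
            mat[i, mask_a], mat[i, mask_b], phi, sizes[mask_a], sizes[mask_b]
        )
        rows.append((name, lfc, p))
    out = pd.DataFrame(rows, columns=["name", "log2fc", "p_value"]).set_index("name")
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    out["direction"] = [
        _direction(l, p) for l, p in zip(out["log2fc"], out["p_value"])
    ]
    out.attrs["contrast"] = label
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# NB log-linear model (interaction test)
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    if phi <= 0:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + y * np.log(mu / (mu + r))
            + r * np.log(r / (mu + r))
        )
    )


def _fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, bool]:
    """IRLS fit of an NB GLM with log link and known dispersion.

    Returns (beta, loglik, converged).
    """
    y = np.asarray(y, dtype=float)
    mu = y + 0.5
    eta = np.log(mu)
    beta = np.linalg.lstsq(X, eta - offset, rcond=None)[0]
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        ll = _nb_loglik(y, np.exp(np.clip(X @ beta_new + offset, -30, 30)), phi)
        step = beta_new - beta
        beta = beta_new
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0) and np.max(np.abs(step)) < 1e-8:
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta + offset, -30, 30)
    return beta, _nb_loglik(y, np.exp(eta), phi), converged


def interaction_test(
    counts: pd.DataFrame,
    genotype: list[str] | np.ndarray,
    condition: list[str] | np.ndarray,
    phi: float,
    lib_sizes: pd.Series,
) -> pd.DataFrame:
    """Genotype x treatment interaction via an NB GLM likelihood-ratio test.

    Requires a 2x2 design with replicates.  The full model
    (1 + genotype + condition + genotype:condition) is compared against the
    reduced model without the interaction; p from chi-square with 1 df.
    The reported log2fc is the interaction coefficient on the log2 scale —
    the difference between the two genotypes' treatment log2 fold changes.
    Non-converged fits get p = NaN.
    """
    genotype = np.asarray(genotype)
    condition = np.asarray(condition)
    g_levels = sorted(pd.unique(genotype))
    c_levels = sorted(pd.unique(condition))
    if len(g_levels) != 2 or len(c_levels) != 2:
        raise ValueError("interaction test requires exactly 2 genotypes and 2 conditions")
    g = (genotype == g_levels[1]).astype(float)
    c = (condition == c_levels[1]).astype(float)
    X_full = np.column_stack([np.ones_like(g), g, c, g * c])
    X_red = X_full[:, :3]
    sizes = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    offset = np.log(sizes)

    rows = []
    for name, row in counts.iterrows():
        y = row.to_numpy(dtype=float)
        if y.sum() == 0:
            rows.append((name, 0.0, 1.0, "ns", True))
            continue
        beta_f, ll_f, conv_f = _fit_nb_glm(y, X_full, offset, phi)
        _, ll_r, conv_r = _fit_nb_glm(y, X_red, offset, phi)
        if not (conv_f and conv_r):
            rows.append((name, np.nan, np.nan, "ns", False))
            continue
        lrt = max(2.0 * (ll_f - ll_r), 0.0)
        p = float(chi2.sf(lrt, df=1))
        lfc = float(beta_f[3] / np.log(2.0))
        rows.append((name, lfc, p, _direction(lfc, p), True))
    out = pd.DataFrame(
        rows, columns=["name", "log2fc", "p_value", "direction", "converged"]
    ).set_index("name")
    out.attrs["contrast"] = (
        f"interaction:({g_levels[1]}-{g_levels[0]})x({c_levels[1]}-{c_levels[0]})"
    )
    return out


# ---------------------------------------------------------------------------
# Set comparison across genotypes
# ---------------------------------------------------------------------------


@dataclass
class SetComparison:
    """Shared / group-exclusive / genotype-specific regulation sets."""

    membership: pd.DataFrame  # miRNA x genotype, values in {up, down, ns}
    shared_up: set[str] = field(default_factory=set)
    shared_down: set[str] = field(default_factory=set)
    group_exclusive: dict[str, set[str]] = field(default_factory=dict)
    genotype_specific: dict[str, set[str]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {"shared_up": len(self.shared_up), "shared_down": len(self.shared_down)}
        out.update({f"exclusive_{k}": len(v) for k, v in self.group_exclusive.items()})
        out.update({f"specific_{k}": len(v) for k, v in self.genotype_specific.items()})
        return out


def compare_sets(
    de_tables: dict[str, pd.DataFrame],
    low_group: list[str] | None = None,
    high_group: list[str] | None = None,
) -> SetComparison:
    """Set arithmetic over per-genotype DE calls.

    ``de_tables`` maps genotype -> DE table (indexed by miRNA, with a
    ``direction`` column).  Mismatched miRNA universes are intersected with
    a warning.  Group-exclusive sets (per direction) contain miRNAs called
    in every member of one chalk group and in no member of the other;
    genotype-specific sets contain miRNAs called in exactly that genotype.
    """
    genotypes = sorted(de_tables)
    universes = [set(t.index) for t in de_tables.values()]
    universe = set.intersection(*universes) if universes else set()
    if universes and universe != set.union(*universes):
        warnings.warn("miRNA universes differ between genotypes; intersecting", stacklevel=2)
    idx = sorted(universe)
    membership = pd.DataFrame(
        {g: de_tables[g].loc[idx, "direction"] for g in genotypes}, index=idx
    )

    def called(g: str, direction: str) -> set[str]:
        col = membership[g]
        return set(col.index[col == direction])

    shared_up = set(idx)
    shared_down = set(idx)
    for g in genotypes:
        shared_up &= called(g, "up")
        shared_down &= called(g, "down")

    group_exclusive: dict[str, set[str]] = {}
    if low_group and high_group:
        groups = {"low": list(low_group), "high": list(high_group)}
        for label, members in groups.items():
            other = groups["high" if label == "low" else "low"]
            for direction in ("up", "down"):
                in_all = set(idx)
                for g in members:
                    in_all &= called(g, direction)
                in_none = set(idx)
                for g in other:
                    in_none -= called(g, direction)
                group_exclusive[f"{label}_{direction}"] = in_all & in_none

    genotype_specific: dict[str, set[str]] = {}
    for g in genotypes:
        others = [h for h in genotypes if h != g]
        for direction in ("up", "down"):
            s = called(g, direction)
            for h in others:
                s -= called(h, direction)
            genotype_specific[f"{g}_{direction}"] = s

    return SetComparison(
        membership=membership,
        shared_up=shared_up,
        shared_down=shared_down,
        group_exclusive=group_exclusive,
        genotype_specific=genotype_specific,
    )
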