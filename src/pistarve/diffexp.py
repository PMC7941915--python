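"""Two-group differential expression of count features by an exact NB test.

The model is the classic exact negative-binomial test for two-group,
unpaired count data: library sizes are equalized by scaling counts to the
geometric-mean library size (pseudo-counts, rounded to integers), a common
dispersion is estimated by conditional maximum likelihood on those
pseudo-counts, and each feature is tested by conditioning on its total
pseudo-count and summing the probabilities of group-A totals no more likely
than the observed one under the NB split.  In the Poisson limit
(dispersion 0) the conditional distribution is binomial and the test
reduces to the conditional binomial exact test.

Fold changes are reported on normalized means as log2(treated / control);
features expressed in exactly one group carry a NaN fold change and an
``exclusive_expression`` flag instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TwoGroupDesign:
    """Sample-to-group assignment for an unpaired two-group comparison.

    ``treated`` is the numerator of the fold change (e.g. low-Pi) and
    ``control`` the denominator.
    """

    samples: tuple
    groups: tuple
    treated: str = "low-Pi"
    control: str = "control"
    organ: str = ""

    def __post_init__(self):
        if len(self.samples) != len(self.groups):
            raise ValueError("samples and groups must have equal length")
        labels = set(self.groups)
        if labels != {self.treated, self.control}:
            raise ValueError(
                f"groups must be exactly {{{self.treated!r}, {self.control!r}}}, got {labels}"
            )
        for g in (self.treated, self.control):
            if sum(x == g for x in self.groups) < 2:
                raise ValueError(f"group {g!r} needs at least 2 samples")

    def mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups])

    def swapped(self) -> "TwoGroupDesign":
        return TwoGroupDesign(
            self.samples, self.groups, treated=self.control, control=self.treated,
            organ=self.organ,
        )


# ---------------------------------------------------------------------------
# Pseudo-counts and dispersion
# ---------------------------------------------------------------------------

def equalize_library_sizes(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to the geometric-mean library size and round.

    The rounded pseudo-counts keep the NB conditioning arguments integral;
    this is a moment-matching simplification of quantile equalization.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).all():
        raise ValueError("all-zero count matrix")
    positive = lib[lib > 0]
    target = float(np.exp(np.log(positive).mean()))
    scaled = counts.astype(float) * (target / lib.replace(0, np.nan))
    return scaled.fillna(0.0).round().astype(np.int64)


def _group_conditional_loglik(y: np.ndarray, r: float) -> np.ndarray:
    """Per-feature NB conditional log-likelihood given the group totals.

    ``y`` is (features x samples within one group); equal library sizes and
    equal means within the group are assumed.  Terms free of the dispersion
    are dropped.
    """
    n = y.shape[1]
    z = y.sum(axis=1)
    return (
        gammaln(y + r).sum(axis=1)
        - y.shape[1] * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )


def estimate_common_dispersion(
    counts: pd.DataFrame, design: TwoGroupDesign, bounds: tuple = (1e-6, 10.0)
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Operates on library-size-equalized pseudo-counts; both groups
    contribute.  Returns a value floored at 0 (the Poisson limit).
    """
    pseudo = equalize_library_sizes(counts)
    keep = pseudo.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("all-zero count matrix")
    ya = pseudo.loc[keep].to_numpy()[:, design.mask(design.treated)].astype(float)
    yb = pseudo.loc[keep].to_numpy()[:, design.mask(design.control)].astype(float)

    def neg_loglik(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        return -(
            _group_conditional_loglik(ya, r).sum() + _group_conditional_loglik(yb, r).sum()
        )

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded"
    )
    phi = float(np.exp(res.x))
    # boundary solution = no evidence of extra-Poisson variation
    if phi <= bounds[0] * 1.5:
        return 0.0
    return phi


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def _conditional_pvalue(za: int, z: int, n_a: int, n_b: int, dispersion: float) -> float:
    """Two-sided exact p: sum of conditional probabilities of group-A totals
    no more likely than the observed one."""
    if z == 0:
        return 1.0
    k = np.arange(z + 1)
    if dispersion <= 0:
        log_probs = stats.binom.logpmf(k, z, n_a / (n_a + n_b))
    else:
        mu = z / (n_a + n_b)
        ra, rb = n_a / dispersion, n_b / dispersion
        pa = ra / (ra + n_a * mu)
        pb = rb / (rb + n_b * mu)
        log_probs = stats.nbinom.logpmf(k, ra, pa) + stats.nbinom.logpmf(z - k, rb, pb)
    log_probs -= np.logaddexp.reduce(log_probs)
    probs = np.exp(log_probs)
    p = float(probs[probs <= probs[za] * (1.0 + 1e-10)].sum())
    if p >= 1.0 - 1e-9:  # observed split is the conditional mode
        return 1.0
    return max(p, np.nextafter(0.0, 1.0))


def exact_nb_test(
    counts: pd.DataFrame, design: TwoGroupDesign, dispersion: float
) -> pd.Series:
    """Per-feature two-sided exact NB p-values on equalized pseudo-counts."""
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    pseudo = equalize_library_sizes(counts)
    mask_a = design.mask(design.treated)
    mask_b = design.mask(design.control)
    za = pseudo.to_numpy()[:, mask_a].sum(axis=1)
    zb = pseudo.to_numpy()[:, mask_b].sum(axis=1)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    pvals = np.ones(len(pseudo))
    for i, (a, b) in enumerate(zip(za, zb)):
        pvals[i] = _conditional_pvalue(int(a), int(a + b), n_a, n_b, dispersion)
    return pd.Series(pvals, index=counts.index, name="p_value")


def adjust_pvalues(pvalues: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Bonferroni (min(1, m*p)) or Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "fdr_bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def compute_log2fc(mean_treated: float, mean_control: float) -> tuple[float, bool]:
    """log2 fold change with the exclusive-expression NaN convention.

    Returns ``(log2fc, exclusive)``: the ratio when both means are positive,
    NaN with ``exclusive=True`` when exactly one mean is zero, and NaN with
    ``exclusive=False`` when both are zero (feature not expressed).
    """
    if mean_treated < 0 or mean_control < 0:
        raise ValueError("means must be non-negative")
    if mean_treated > 0 and mean_control > 0:
        return float(np.log2(mean_treated / mean_control)), False
    if mean_treated == 0 and mean_control == 0:
        return float("nan"), False
    return float("nan"), True


# ---------------------------------------------------------------------------
# Full two-group analysis and DEM/DES selection
# ---------------------------------------------------------------------------

def run_two_group(
    counts: pd.DataFrame,
    design: TwoGroupDesign,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Exact NB differential expression of a count table.

    Features with zero counts in all samples are dropped before the number
    of tests is counted.  Returns one row per retained feature with
    normalized (per-million) group means, log2 fold change (NaN with the
    ``exclusive_expression`` flag when one group is silent), raw and
    Bonferroni/BH-adjusted p-values.
    """
    counts = counts.loc[counts.sum(axis=1) > 0]
    if counts.empty:
        raise ValueError("all-zero count matrix")
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, design)
    lib = counts.sum(axis=0).astype(float)
    norm = counts.astype(float) * 1e6 / lib
    mean_a = norm.loc[:, design.mask(design.treated)].mean(axis=1)
    mean_b = norm.loc[:, design.mask(design.control)].mean(axis=1)
    p = exact_nb_test(counts, design, dispersion)
    lfc = np.empty(len(counts))
    exclusive = np.empty(len(counts), dtype=bool)
    for i, (a, b) in enumerate(zip(mean_a.to_numpy(), mean_b.to_numpy())):
        lfc[i], exclusive[i] = compute_log2fc(a, b)
    return pd.DataFrame(
        {
            "mean_normalized_treated": mean_a,
            "mean_normalized_control": mean_b,
            "log2fc": lfc,
            "exclusive_expression": exclusive,
            "p_value": p,
            "p_bonferroni": adjust_pvalues(p, "bonferroni"),
            "p_fdr": adjust_pvalues(p, "fdr_bh"),
        },
        index=counts.index,
    )


def select_dems_dess(
    results: pd.DataFrame, layers: pd.Series, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split Bonferroni-significant features into DEMs and DESs.

    DEM = miRBase-exact-annotated features with Bonferroni p < alpha;
    DES = every other feature with Bonferroni p < alpha (strict inequality).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    significant = results[results["p_bonferroni"] < alpha]
    layer = layers.reindex(significant.index).fillna("unannotated")
    dems = significant[layer == "mirbase_exact"].copy()
    dess = significant[layer != "mirbase_exact"].copy()
    for df in (dems, dess):
        df["direction"] = np.where(
            df["exclusive_expression"],
            np.where(df["mean_normalized_treated"] > 0, "up", "down"),
            np.where(df["log2fc"] > 0, "up", "down"),
        )
    return dems, dess
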