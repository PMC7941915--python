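"""Transcript quantification (RPKM/TPM), DEG selection and chromosome summaries.

RPKM = total exon reads / (mapped reads (millions) x exon length (kb));
TPM  = RPKM x 10^6 / sum(RPKM), per sample, so each sample's TPM vector sums
to one million whenever anything is expressed.

DEGs are called by a two-group negative-binomial likelihood-ratio test
(log link).  For a saturated two-group model with fixed dispersion the
maximum-likelihood fitted means are the group sample means, so the LRT
statistic is evaluated in closed form and compared to chi-square with one
degree of freedom; Bonferroni-adjusted p < alpha (strict) selects DEGs.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .diffexp import TwoGroupDesign, adjust_pvalues, compute_log2fc, estimate_common_dispersion


# ---------------------------------------------------------------------------
# RPKM / TPM
# ---------------------------------------------------------------------------

def compute_rpkm_tpm(
    counts: pd.DataFrame,
    exon_lengths: pd.Series,
    mapped_reads: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the RPKM and TPM formulas per sample.

    ``exon_lengths`` is in bases; ``mapped_reads`` defaults to the per-sample
    count totals.  Returns (rpkm, tpm) tables aligned with ``counts``.
    """
    exon_lengths = exon_lengths.reindex(counts.index)
    if exon_lengths.isna().any():
        missing = exon_lengths.index[exon_lengths.isna()][0]
        raise ValueError(f"missing exon length for {missing!r}")
    if (exon_lengths <= 0).any():
        raise ValueError("exon lengths must be positive")
    if mapped_reads is None:
        mapped_reads = counts.sum(axis=0)
    if (mapped_reads <= 0).any():
        bad = mapped_reads.index[(mapped_reads <= 0).argmax()]
        raise ValueError(f"zero mapped reads for sample {bad!r}")
    length_kb = exon_lengths.astype(float) / 1e3
    rpkm = counts.astype(float).div(mapped_reads / 1e6, axis=1).div(length_kb, axis=0)
    totals = rpkm.sum(axis=0)
    tpm = rpkm * 1e6 / totals.replace(0, np.nan)
    return rpkm, tpm.fillna(0.0)


# ---------------------------------------------------------------------------
# NB GLM likelihood-ratio DEG test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Row-wise NB log-likelihood (Poisson at dispersion 0)."""
    mu = np.maximum(mu, 1e-12)
    if dispersion <= 0:
        return (y * np.log(mu) - mu - gammaln(y + 1)).sum(axis=-1)
    r = 1.0 / dispersion
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    ).sum(axis=-1)


def nb_lrt(
    counts: pd.DataFrame, design: TwoGroupDesign, dispersion: float,
    equalize: bool = True,
) -> pd.DataFrame:
    """Closed-form two-group NB likelihood-ratio test.

    With ``equalize`` (the default) counts are scaled to equal library sizes
    before fitting so the group effect is not confounded with sequencing
    depth.
    """
    if equalize:
        lib = counts.sum(axis=0).astype(float)
        if (lib == 0).all():
            raise ValueError("all-zero count matrix")
        target = float(np.exp(np.log(lib[lib > 0]).mean()))
        y = (counts.astype(float) * (target / lib.replace(0, np.nan))).fillna(0.0).to_numpy()
    else:
        y = counts.astype(float).to_numpy()
    mask_a = design.mask(design.treated)
    mask_b = design.mask(design.control)
    ya, yb = y[:, mask_a], y[:, mask_b]
    mean_a = ya.mean(axis=1)
    mean_b = yb.mean(axis=1)
    mean_0 = y.mean(axis=1)
    ll_full = _nb_loglik(ya, mean_a[:, None], dispersion) + _nb_loglik(
        yb, mean_b[:, None], dispersion
    )
    ll_null = _nb_loglik(y, mean_0[:, None], dispersion)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    return pd.DataFrame(
        {"mean_treated": mean_a, "mean_control": mean_b, "lrt": lrt, "p_value": p},
        index=counts.index,
    )


def test_deg(
    counts: pd.DataFrame,
    design: TwoGroupDesign,
    transcripts: Optional[dict] = None,
    dispersion: Optional[float] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call DEGs by the NB LRT with Bonferroni < alpha (strict).

    Returns one row per selected gene with log2fc, Bonferroni p, direction
    and chromosome (when transcript models are supplied).  Spike-in
    identifiers (ERCC/SIRV prefixes) are flagged but not treated specially.
    """
    spikes = [i for i in counts.index if str(i).startswith(("ERCC", "SIRV"))]
    if spikes:
        warnings.warn(f"{len(spikes)} spike-in ids present but unhandled", stacklevel=2)
    counts = counts.loc[counts.sum(axis=1) > 0]
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, design)
    table = nb_lrt(counts, design, dispersion)
    table["p_bonferroni"] = adjust_pvalues(table["p_value"], "bonferroni")
    lfc = np.empty(len(table))
    exclusive = np.empty(len(table), dtype=bool)
    for i, (a, b) in enumerate(zip(table["mean_treated"], table["mean_control"])):
        lfc[i], exclusive[i] = compute_log2fc(a, b)
    table["log2fc"] = lfc
    table["exclusive_expression"] = exclusive
    selected = table[table["p_bonferroni"] < alpha].copy()
    selected["direction"] = np.where(
        selected["exclusive_expression"],
        np.where(selected["mean_treated"] > 0, "up", "down"),
        np.where(selected["log2fc"] > 0, "up", "down"),
    )
    if transcripts is not None:
        selected["chromosome"] = [
            transcripts[g].chromosome if g in transcripts else "0H" for g in selected.index
        ]
    return selected


# ---------------------------------------------------------------------------
# Chromosome distribution
# ---------------------------------------------------------------------------

def chromosome_distribution(degs: pd.DataFrame, transcripts: dict) -> pd.DataFrame:
    """Per-chromosome up/down DEG counts and percentages of each
    chromosome's protein-coding gene total.

    Unknown chromosome labels are counted under "0H" with a warning.
    """
    coding_totals: dict[str, int] = {}
    known = set()
    for model in transcripts.values():
        known.add(model.chromosome)
        if model.cdna_class == "protein-coding":
            coding_totals[model.chromosome] = coding_totals.get(model.chromosome, 0) + 1
    rows: dict[str, dict] = {}
    for gene, row in degs.iterrows():
        chrom = transcripts[gene].chromosome if gene in transcripts else None
        if chrom is None or chrom not in known:
            warnings.warn(f"unknown chromosome for {gene!r}; counted under 0H", stacklevel=2)
            chrom = "0H"
        entry = rows.setdefault(chrom, {"up": 0, "down": 0})
        entry[row["direction"]] += 1
    chroms = sorted(set(coding_totals) | set(rows))
    table = pd.DataFrame(
        {
            "up": [rows.get(c, {}).get("up", 0) for c in chroms],
            "down": [rows.get(c, {}).get("down", 0) for c in chroms],
            "protein_coding_total": [coding_totals.get(c, 0) for c in chroms],
        },
        index=pd.Index(chroms, name="chromosome"),
    )
    total = table["protein_coding_total"].replace(0, np.nan)
    table["percent_of_chromosome_genes"] = (
        100.0 * (table["up"] + table["down"]) / total
    ).fillna(0.0).round(2)
    return table
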