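"""Age-variable transcriptome analysis of the fly's second antennal segment.

The ageing stage of the pipeline: pairwise differential expression between
consecutive profiled ages, classification of age-variable vs constant genes by
the fold-change/FDR/p filter, GO-term enrichment scoring, ortholog/deafness
gene-panel overlap tables, preparation of gene lists for motif-based
transcription-factor prediction, and filtering of the returned TF candidates.

The DE test is a deliberately simple stand-in for a full DESeq2-style
analysis: a per-gene negative-binomial model with median-of-ratios size
factors, method-of-moments dispersion, and a Wald-type test on the log fold
change referenced to a t distribution (the plug-in dispersion at 2-3
replicates makes a normal reference anti-conservative). Its calibration is
validated by simulation, not by agreement with any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata import AgeSeriesCounts

__all__ = [
    "DEComparison",
    "AgeVariableSet",
    "EnrichmentResult",
    "OrthologOverlap",
    "pairwise_de",
    "classify_age_variable",
    "go_enrichment",
    "ortholog_overlap",
    "prepare_submission_lists",
    "filter_tf_candidates",
]


@dataclass
class DEComparison:
    """One pairwise age comparison: per-gene log2 FC, raw p and BH FDR."""

    pair: str  # e.g. "d1_vs_d5"
    age_a: object
    age_b: object
    table: pd.DataFrame  # index gene_id; columns log2fc, base_mean, p, fdr


@dataclass
class AgeVariableSet:
    """Genes changing expression in >= 1 pairwise comparison, plus provenance."""

    variable: set
    constant: set
    expressed: set
    qualifying: pd.DataFrame  # gene_id, pair, log2fc, p, fdr (one row per hit)

    @property
    def constant_fraction_pct(self) -> float:
        """Percentage of expressed genes with constant expression (integer-rounded)."""
        return round(100.0 * len(self.constant) / len(self.expressed))


@dataclass
class EnrichmentResult:
    """GO-term enrichment: score (b/n)/(B/N) and hypergeometric tail p."""

    term: str
    b: int  # target genes carrying the term
    n: int  # target-set size
    B: int  # background genes carrying the term
    N: int  # background size
    enrichment: float
    p_value: float


@dataclass
class OrthologOverlap:
    """Overlap of a foreign gene panel with the expressed / age-variable sets."""

    panel_size: int
    conserved_expressed: int
    conserved_expressed_pct: float
    age_variable: int
    age_variable_pct: float  # of the conserved-and-expressed genes
    genes_conserved_expressed: list
    genes_age_variable: list


# ---------------------------------------------------------------------------
# differential expression


def _size_factors(counts: pd.DataFrame) -> np.ndarray:
    """DESeq-style median-of-ratios size factors (total-count fallback)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = np.log(counts.to_numpy(dtype=float))
        logmeans = np.nanmean(np.where(np.isfinite(logc), logc, np.nan), axis=1)
    usable = np.isfinite(logmeans) & np.all(np.isfinite(logc), axis=1)
    if usable.sum() >= 50:
        sf = np.exp(np.median(logc[usable] - logmeans[usable, None], axis=0))
    else:
        tot = counts.sum(axis=0).to_numpy(dtype=float)
        sf = tot / np.median(tot)  # exact for equal library sizes
    return sf


def pairwise_de(counts: AgeSeriesCounts, pair: tuple) -> DEComparison:
    """Negative-binomial Wald test between two ages, BH-adjusted.

    Per gene, normalized means and within-group moments give a
    method-of-moments dispersion (var = mu + alpha mu^2, alpha >= 0 pooled
    across the two groups); the Wald statistic on the natural-log fold change
    uses the delta-method variance (1/mu + alpha)/n per group and a t reference
    with n_a + n_b - 2 degrees of freedom. Genes with all-zero counts in both
    groups get log2fc = 0, p = 1.
    """
    age_a, age_b = pair
    samples_a = counts.samples_for_age(age_a)
    samples_b = counts.samples_for_age(age_b)
    for age, s in ((age_a, samples_a), (age_b, samples_b)):
        if not s:
            raise ValueError(f"age {age!r} not present in the sample sheet")
        if len(s) < 2:
            raise ValueError(f"age {age!r} has a single replicate; need >= 2")

    sub = counts.counts[samples_a + samples_b]
    sf = _size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf
    na, nb = len(samples_a), len(samples_b)
    A, B = norm[:, :na], norm[:, na:]

    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    var_a, var_b = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)

    # pooled MoM dispersion: weighted residual var over weighted mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = ((na - 1) * (var_a - mu_a) + (nb - 1) * (var_b - mu_b)) / (
            (na - 1) * mu_a**2 + (nb - 1) * mu_b**2
        )
    alpha = np.clip(np.nan_to_num(alpha, nan=0.0), 0.0, None)

    pseudo = 0.5
    lfc = np.log(mu_b + pseudo) - np.log(mu_a + pseudo)
    with np.errstate(divide="ignore"):
        se2 = (1.0 / np.maximum(mu_a, pseudo) + alpha) / na + (
            1.0 / np.maximum(mu_b, pseudo) + alpha
        ) / nb
    wald = lfc / np.sqrt(se2)
    df = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(wald), df)

    allzero = (sub.sum(axis=1) == 0).to_numpy()
    lfc[allzero] = 0.0
    p[allzero] = 1.0

    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2fc": lfc / np.log(2.0),
            "base_mean": (mu_a + mu_b) / 2.0,
            "p": p,
            "fdr": fdr,
        },
        index=sub.index,
    )
    return DEComparison(pair=f"d{age_a}_vs_d{age_b}", age_a=age_a, age_b=age_b, table=table)


def classify_age_variable(
    comparisons: list[DEComparison],
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.10,
    p_threshold: float = 0.05,
) -> AgeVariableSet:
    """Partition expressed genes into age-variable and constant sets.

    A gene is age-variable iff, in at least one comparison, its fold change
    strictly exceeds ``fc_threshold`` (in either direction) AND its BH FDR is
    below ``fdr_threshold`` AND its raw p is below ``p_threshold``. The
    complement within the expressed set is the constant-expression set.
    """
    if not comparisons:
        raise ValueError("need >= 1 comparison")
    for thr, name in ((fc_threshold, "fc"), (fdr_threshold, "fdr"), (p_threshold, "p")):
        if thr <= 0 or (name != "fc" and thr > 1):
            raise ValueError(f"{name} threshold out of range")
    expressed: set = set()
    hits = []
    for comp in comparisons:
        t = comp.table
        expressed |= set(t.index)
        fc = 2.0 ** t["log2fc"].abs()
        keep = (fc > fc_threshold) & (t["fdr"] < fdr_threshold) & (t["p"] < p_threshold)
        for gene, row in t[keep].iterrows():
            hits.append(
                {
                    "gene_id": gene,
                    "pair": comp.pair,
                    "log2fc": row["log2fc"],
                    "p": row["p"],
                    "fdr": row["fdr"],
                    "direction": "up" if row["log2fc"] > 0 else "down",
                }
            )
    qualifying = pd.DataFrame(hits, columns=["gene_id", "pair", "log2fc", "p", "fdr", "direction"])
    variable = set(qualifying["gene_id"]) if len(qualifying) else set()
    return AgeVariableSet(
        variable=variable,
        constant=expressed - variable,
        expressed=expressed,
        qualifying=qualifying,
    )


# ---------------------------------------------------------------------------
# enrichment and overlap arithmetic


def go_enrichment(target: set, term_sets: dict, background: set) -> list[EnrichmentResult]:
    """Score GO terms by Enrichment = (b/n)/(B/N) with a hypergeometric tail p.

    ``b`` counts target genes annotated to the term, ``n`` the target size,
    ``B`` the background genes annotated to the term, ``N`` the background
    size; p = P(X >= b) for X ~ Hypergeom(N, B, n). Results are sorted by p.
    Terms absent from the background are skipped; b = 0 scores 0 with p = 1.
    """
    target = set(target)
    background = set(background)
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    if not target <= background:
        raise ValueError("target set must be a subset of the background")
    N = len(background)
    n = len(target)
    out = []
    for term, genes in term_sets.items():
        term_genes = set(genes) & background
        B = len(term_genes)
        if B == 0:
            continue
        b = len(term_genes & target)
        enrichment = (b / n) / (B / N)
        p = float(stats.hypergeom.sf(b - 1, N, B, n)) if b > 0 else 1.0
        out.append(
            EnrichmentResult(term=term, b=b, n=n, B=B, N=N, enrichment=enrichment, p_value=p)
        )
    out.sort(key=lambda r: (r.p_value, -r.enrichment, r.term))
    return out


def _pct(numer: int, denom: int, decimals: int) -> float:
    if denom == 0:
        return 0.0
    return round(100.0 * numer / denom, decimals) if decimals else round(100.0 * numer / denom)


def ortholog_overlap(
    mapping: pd.DataFrame,
    expressed: set,
    age_variable: set,
    gene_panel: set,
    panel_namespace: str = "foreign",
    decimals: int = 0,
) -> OrthologOverlap:
    """Overlap a foreign (mouse/human) gene panel with the fly expression sets.

    ``mapping`` is a two-column frame (fly_gene, foreign_gene); duplicate rows
    are collapsed with a warning. A panel gene counts as conserved-and-expressed
    when at least one fly ortholog is in ``expressed``; it counts as
    age-variable when at least one such ortholog is in ``age_variable``.
    Percentages are rounded to ``decimals`` places (matching how each table
    caption prints them) and are exactly recomputable from the integer counts.
    """
    cols = list(mapping.columns[:2])
    m = mapping[cols].rename(columns={cols[0]: "fly", cols[1]: "foreign"})
    ndup = len(m) - len(m.drop_duplicates())
    if ndup:
        import warnings

        warnings.warn(f"collapsed {ndup} duplicate mapping rows")
        m = m.drop_duplicates()
    key = "foreign" if panel_namespace == "foreign" else "fly"
    other = "fly" if key == "foreign" else "foreign"

    conserved_expressed, variable = [], []
    for g in sorted(gene_panel):
        orthologs = set(m.loc[m[key] == g, other])
        if orthologs & expressed:
            conserved_expressed.append(g)
            if orthologs & age_variable:
                variable.append(g)
    return OrthologOverlap(
        panel_size=len(gene_panel),
        conserved_expressed=len(conserved_expressed),
        conserved_expressed_pct=_pct(len(conserved_expressed), len(gene_panel), decimals),
        age_variable=len(variable),
        age_variable_pct=_pct(len(variable), len(conserved_expressed), decimals),
        genes_conserved_expressed=conserved_expressed,
        genes_age_variable=variable,
    )


# ---------------------------------------------------------------------------
# motif-tool submission lists and TF candidate filtering


SUBMISSION_ROUNDS = ("I", "II", "III")


def prepare_submission_lists(
    age_variable: AgeVariableSet,
    counts: AgeSeriesCounts | None = None,
    go_groups: dict | None = None,
    round: str = "I",
    reads_threshold: float = 10_000.0,
    fc_round3: float = 4.0,
) -> list[str]:
    """Build the gene list for one motif-analysis submission round.

    Round I: age-variable genes within the configured hearing-relevant GO
    groups (trafficking, structural, dynein motors, receptors). Round II:
    age-variable genes whose mean normalized count strictly exceeds
    ``reads_threshold``. Round III: age-variable genes moving at least
    ``fc_round3``-fold (inclusive) in >= 1 comparison. Lists are sorted,
    one gene id per line when written.
    """
    if round not in SUBMISSION_ROUNDS:
        raise ValueError(f"unknown submission round {round!r}; expected one of {SUBMISSION_ROUNDS}")
    variable = age_variable.variable
    if round == "I":
        if not go_groups:
            raise ValueError("round I needs the hearing-relevant GO groups")
        selected: set = set()
        for name, genes in go_groups.items():
            genes = set(genes) & variable
            if not genes:
                import warnings

                warnings.warn(f"GO group {name!r} contributes no age-variable genes")
            selected |= genes
        return sorted(selected)
    if round == "II":
        if counts is None:
            raise ValueError("round II needs the count matrix")
        sf = _size_factors(counts.counts)
        mean_norm = (counts.counts.to_numpy(dtype=float) / sf).mean(axis=1)
        means = pd.Series(mean_norm, index=counts.counts.index)
        return sorted(g for g in variable if g in means.index and means[g] > reads_threshold)
    # round III: |FC| >= 4 in at least one comparison (inclusive boundary)
    q = age_variable.qualifying
    if not len(q):
        return []
    maxfc = q.assign(absfc=2.0 ** q["log2fc"].abs()).groupby("gene_id")["absfc"].max()
    return sorted(maxfc.index[maxfc >= fc_round3])


def filter_tf_candidates(
    candidates: pd.DataFrame,
    expressed: set,
    nes_threshold: float = 2.5,
    id_column: str = "gene_id",
    nes_column: str = "NES",
) -> pd.DataFrame:
    """Keep motif-predicted TF candidates that are expressed and score >= NES cut-off.

    The NES boundary is inclusive (a candidate at exactly the threshold is
    retained).
    """
    if id_column not in candidates.columns:
        raise ValueError(f"candidate table lacks the id column {id_column!r}")
    out = candidates[candidates[id_column].isin(expressed)]
    if nes_column in out.columns:
        out = out[out[nes_column] >= nes_threshold]
    return out.reset_index(drop=True)
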