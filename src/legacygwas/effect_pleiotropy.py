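"""Pleiotropy analysis of a peak: standardized effects and haplotype groups.

Two complementary views of how one genomic region touches many traits:

* ``standardized_effects`` refits the mixed-model GLS for chosen peak
  markers against z-scored phenotypes, so the absolute marker effects
  |beta| are in standard-deviation units and comparable across traits
  (radar-chart style effect tables).
* ``assign_haplotypes`` + ``pleiotropy_panel`` group varieties by the
  functional/null status of user-defined gene haplotypes (e.g. an
  anthocyanin switch gene crossed with a tone gene), then compare trait
  distributions across groups with a one-way ANOVA followed by
  Tukey-Kramer HSD (unequal group sizes) and a compact letter display:
  groups sharing a letter are not significantly different.

The Tukey-Kramer adjusted p-values are computed directly from the
studentized range distribution; letters come from the maximal cliques of
the non-significance graph, so the letter-sharing relation reproduces the
pairwise test outcomes exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypePanel
from .mixed_model_scan import KinshipMatrix, scan_quantitative
from .trait_prep import PhenotypeVector

log = logging.getLogger(__name__)


@dataclass
class EffectTable:
    """|beta| per (peak marker, trait), effects in trait-SD units."""

    table: pd.DataFrame  # rows = marker ids, columns = trait names

    def normalized(self) -> pd.DataFrame:
        """Per-trait max-normalized variant for radar-style display."""
        denom = self.table.max(axis=0).replace(0.0, 1.0)
        return self.table / denom


@dataclass
class GeneHaplotypeDef:
    """Defining polymorphisms and functionality classes of one gene.

    ``haplotypes`` maps a haplotype label to the dict of
    ``{marker_id: allele_dosage}`` that defines it; ``functionality`` maps
    every haplotype label to "functional" or "null".
    """

    gene_label: str
    haplotypes: dict[str, dict[str, int]]
    functionality: dict[str, str]

    def __post_init__(self) -> None:
        for hap in self.haplotypes:
            if hap not in self.functionality:
                raise ValueError(f"haplotype {hap!r} has no functionality class")
        for hap, cls in self.functionality.items():
            if cls not in ("functional", "null"):
                raise ValueError(f"functionality must be functional/null, got {cls!r}")


@dataclass
class GroupComparison:
    groups: dict[str, list[str]]
    anova_p: float
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, q, p_adj
    tukey_letters: dict[str, str]
    group_stats: pd.DataFrame  # n, mean, q25, median, q75 per group
    ns: bool = False
    trait_name: str = ""
    dropped_groups: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# standardized effects
# ---------------------------------------------------------------------------

def standardized_effects(panel: GenotypePanel, traits: list[PhenotypeVector],
                         peak_markers: list[str],
                         kinship: KinshipMatrix) -> EffectTable:
    """Mixed-model |beta| of each peak marker on each standardized trait.

    Every phenotype must carry ``provenance="standardized"``; the same GLS
    machinery as the genome scan is used, so each entry is reproducible
    from a scan of the standardized trait.
    """
    for t in traits:
        if t.provenance != "standardized":
            raise ValueError(f"trait {t.trait_name!r} is not standardized")
    idx = [panel.marker_index(m) for m in peak_markers]
    sub = panel.subset_markers(np.array(sorted(set(idx))))
    cols = {}
    for t in traits:
        scan = scan_quantitative(sub, t.values, kinship)
        by_id = scan.df.set_index("id")["beta"]
        cols[t.trait_name] = [abs(float(by_id[m])) for m in peak_markers]
    return EffectTable(pd.DataFrame(cols, index=pd.Index(peak_markers, name="marker")))


# ---------------------------------------------------------------------------
# haplotype assignment
# ---------------------------------------------------------------------------

def assign_haplotypes(panel: GenotypePanel,
                      gene_def: GeneHaplotypeDef) -> pd.DataFrame:
    """Match each variety to a defined haplotype of one gene.

    Imputed dosages are rounded to the nearest integer for matching; a
    heterozygous call at a defining marker, or a combination matching no
    defined haplotype, yields "unassigned" (these inbred panels are
    expected homozygous).  Returns a DataFrame indexed by variety with
    columns ``haplotype`` and ``functionality``.
    """
    marker_ids = sorted({m for alleles in gene_def.haplotypes.values() for m in alleles})
    cols = {m: np.round(panel.dosages[:, panel.marker_index(m)]) for m in marker_ids}
    haplotype = []
    functionality = []
    n_het = 0
    for i in range(panel.n_varieties):
        call = {m: cols[m][i] for m in marker_ids}
        if any(np.isnan(v) for v in call.values()):
            haplotype.append("unassigned"); functionality.append("unassigned")
            continue
        if any(v == 1 for v in call.values()):
            n_het += 1
            haplotype.append("unassigned"); functionality.append("unassigned")
            continue
        matched = None
        for hap, alleles in gene_def.haplotypes.items():
            if all(call.get(m) == d for m, d in alleles.items()):
                matched = hap
                break
        if matched is None:
            haplotype.append("unassigned"); functionality.append("unassigned")
        else:
            haplotype.append(matched)
            functionality.append(gene_def.functionality[matched])
    if n_het:
        log.info("%s: %d varieties heterozygous at defining markers -> unassigned",
                 gene_def.gene_label, n_het)
    return pd.DataFrame({"haplotype": haplotype, "functionality": functionality},
                        index=pd.Index(panel.varieties, name="variety"))


# ---------------------------------------------------------------------------
# Tukey-Kramer HSD with compact letter display
# ---------------------------------------------------------------------------

def tukey_kramer(samples: dict[str, np.ndarray]) -> tuple[pd.DataFrame, int, float]:
    """All-pairs Tukey-Kramer HSD for (possibly unequal-n) groups.

    Returns (pairwise table, residual df, MSE).  Adjusted p-values come
    from the studentized range distribution with k groups and N - k df.
    """
    labels = list(samples)
    k = len(labels)
    ns = np.array([len(samples[g]) for g in labels])
    means = np.array([float(np.mean(samples[g])) for g in labels])
    N = int(ns.sum())
    dfres = N - k
    if dfres < 1:
        raise ValueError("no residual degrees of freedom")
    sse = sum(float(np.sum((samples[g] - means[i]) ** 2))
              for i, g in enumerate(labels))
    mse = sse / dfres
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[j] - means[i]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se if se > 0 else np.inf
        p_adj = float(stats.studentized_range.sf(q, k, dfres)) if np.isfinite(q) else 0.0
        rows.append((labels[i], labels[j], diff, q, min(p_adj, 1.0)))
    table = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "q", "p_adj"])
    return table, dfres, mse


def _maximal_cliques(nodes: list[str], edges: set[frozenset]) -> list[set]:
    """Bron-Kerbosch (no pivoting; group counts are small)."""
    adj = {v: set() for v in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    cliques: list[set] = []

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in list(p):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(nodes), set())
    return cliques


def compact_letters(groups: list[str], nonsig_pairs: set[frozenset],
                    order_by: dict[str, float] | None = None) -> dict[str, str]:
    """Letter display from the non-significance graph.

    Letters are the maximal cliques of the graph whose edges are the
    non-significant pairs, so two groups share a letter iff they are not
    significantly different.  Cliques are lettered in order of the best
    (e.g. highest-mean) group they contain.
    """
    cliques = _maximal_cliques(groups, nonsig_pairs)
    for g in groups:  # isolated groups form singleton cliques
        if not any(g in c for c in cliques):
            cliques.append({g})
    keyfun = (lambda c: min(-order_by[g] for g in c)) if order_by else \
             (lambda c: min(groups.index(g) for g in c))
    cliques.sort(key=keyfun)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for li, c in enumerate(cliques):
        for g in groups:
            if g in c:
                letters[g] += alphabet[li % len(alphabet)]
    return letters


def group_compare(trait: PhenotypeVector, groups: dict[str, list[str]],
                  alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA across variety groups, then Tukey-Kramer HSD letters.

    Groups with fewer than 2 phenotyped members are dropped with a warning.
    If the ANOVA is not significant at ``alpha`` the comparison is flagged
    NS and all groups share one letter; otherwise letters encode the
    pairwise Tukey outcomes (adjusted p exactly at ``alpha`` counts as
    non-significant).
    """
    samples: dict[str, np.ndarray] = {}
    dropped = []
    for label, members in groups.items():
        vals = trait.values.reindex(members).dropna().to_numpy()
        if len(vals) < 2:
            dropped.append(label)
            log.warning("group %r has n=%d < 2; dropped", label, len(vals))
            continue
        samples[label] = vals
    if len(samples) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    labels = list(samples)
    anova_p = float(stats.f_oneway(*samples.values()).pvalue)
    tukey_table, _, _ = tukey_kramer(samples)
    means = {g: float(np.mean(samples[g])) for g in labels}
    if anova_p >= alpha:
        letters = {g: "a" for g in labels}
        ns = True
    else:
        nonsig = {frozenset((r.group1, r.group2))
                  for r in tukey_table.itertuples() if r.p_adj >= alpha}
        letters = compact_letters(labels, nonsig, order_by=means)
        ns = False
    stats_df = pd.DataFrame({
        "n": [len(samples[g]) for g in labels],
        "mean": [means[g] for g in labels],
        "q25": [float(np.quantile(samples[g], 0.25)) for g in labels],
        "median": [float(np.median(samples[g])) for g in labels],
        "q75": [float(np.quantile(samples[g], 0.75)) for g in labels],
    }, index=pd.Index(labels, name="group"))
    return GroupComparison(groups={g: list(groups[g]) for g in labels},
                           anova_p=anova_p, tukey=tukey_table,
                           tukey_letters=letters, group_stats=stats_df,
                           ns=ns, trait_name=trait.trait_name,
                           dropped_groups=dropped)


def pleiotropy_panel(panel: GenotypePanel, gene_defs: list[GeneHaplotypeDef],
                     traits: list[PhenotypeVector],
                     alpha: float = 0.05) -> list[GroupComparison]:
    """Cross-classify varieties by gene functionality and compare each trait.

    Group labels cross the functional/null status of every gene (upper-case
    for functional, lower-case for null, e.g. "SWITCH/tone"); unassigned
    varieties and empty cross-classes are omitted.
    """
    if not gene_defs or not traits:
        raise ValueError("need >= 1 gene definition and >= 1 trait")
    assigns = [assign_haplotypes(panel, gd) for gd in gene_defs]
    labels = []
    for i, v in enumerate(panel.varieties):
        parts = []
        ok = True
        for gd, a in zip(gene_defs, assigns):
            fn = a.iloc[i]["functionality"]
            if fn == "unassigned":
                ok = False
                break
            parts.append(gd.gene_label.upper() if fn == "functional"
                         else gd.gene_label.lower())
        labels.append("/".join(parts) if ok else None)
    groups: dict[str, list[str]] = {}
    for v, lab in zip(panel.varieties, labels):
        if lab is not None:
            groups.setdefault(lab, []).append(v)
    out = []
    for t in traits:
        out.append(group_compare(t, groups, alpha=alpha))
    return out
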