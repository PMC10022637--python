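"""Genotype and phenotype containers, VCF/TSV input-output, marker QC.

The two cohorts under comparison (a panel scored with legacy database
phenotypes and a panel with newly measured phenotypes) are genotyped
independently, possibly on different marker sets.  This module holds the
in-memory representation of a genotyped panel and of a long-format trait
table, reads/writes them as VCFv4.2 and TSV, applies the marker quality
filter (missing rate and minor allele frequency), mean-imputes residual
missing calls, and reconciles the marker sets of two panels by genomic
position and allele identity.

Conventions
-----------
* dosages are alt-allele counts in {0, 1, 2}; missing calls are ``NaN``;
  after imputation dosages may be non-integral.
* VCF coordinates are 1-based; region bounds elsewhere in the package are
  half-open ``[start, end)`` in bp.
* INDELs are treated exactly like SNPs; allele matching is by exact string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]
TRAIT_COLUMNS = ["variety", "trait", "location", "year", "value"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """A set of varieties genotyped at a common, position-sorted marker set.

    Attributes
    ----------
    markers : pandas.DataFrame
        One row per marker with columns ``id, chrom, pos, ref, alt``,
        sorted by ``(chrom, pos)``.
    varieties : list of str
        Unique sample labels, one per dosage-matrix row.
    dosages : numpy.ndarray, shape (n_varieties, n_markers)
        Alt-allele dosage; ``NaN`` marks a missing call.
    """

    markers: pd.DataFrame
    varieties: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if list(self.markers.columns[:5]) != MARKER_COLUMNS:
            raise ValueError(f"marker table must have columns {MARKER_COLUMNS}")
        if self.dosages.shape != (len(self.varieties), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.varieties)} varieties x {len(self.markers)} markers"
            )
        if len(set(self.varieties)) != len(self.varieties):
            raise ValueError("variety labels must be unique")
        if (self.markers["pos"] < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")
        if (self.markers["ref"] == self.markers["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        key = self.markers[["chrom", "pos", "ref", "alt"]]
        if key.duplicated().any():
            raise ValueError("(chrom, pos, ref, alt) must be unique")
        order = self.markers.sort_values(["chrom", "pos"], kind="stable").index
        if not (order.to_numpy() == np.arange(len(order))).all():
            raise ValueError("markers must be sorted by (chrom, pos)")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    # -- convenience -------------------------------------------------------
    @property
    def n_varieties(self) -> int:
        return len(self.varieties)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        idx = self.markers.index[self.markers["id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"marker {marker_id!r} not in panel")
        return int(idx[0])

    def subset_markers(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices, dtype=int)
        return GenotypePanel(
            self.markers.iloc[indices].reset_index(drop=True),
            list(self.varieties),
            self.dosages[:, indices].copy(),
        )

    def subset_varieties(self, names: list[str]) -> "GenotypePanel":
        pos = {v: i for i, v in enumerate(self.varieties)}
        rows = [pos[v] for v in names]
        return GenotypePanel(self.markers.copy(), list(names), self.dosages[rows, :].copy())

    def allele_freqs(self) -> np.ndarray:
        """Alt-allele frequency per marker from non-missing dosages."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)


@dataclass
class TraitTable:
    """Long-format phenotype records with a per-trait type designation.

    ``df`` has columns ``variety, trait, location, year, value``;
    ``trait_types`` maps each trait name to ``"quantitative"`` or
    ``"binary"`` (binary values must be coded 0/1).
    """

    df: pd.DataFrame
    trait_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"trait table missing columns {missing}")
        if self.df[["variety", "trait", "location", "year"]].duplicated().any():
            raise ValueError("duplicate (variety, trait, location, year) records")
        for trait, kind in self.trait_types.items():
            if kind not in ("quantitative", "binary"):
                raise ValueError(f"unknown trait type {kind!r} for {trait!r}")
            if kind == "binary":
                vals = self.df.loc[self.df["trait"] == trait, "value"].dropna()
                if not vals.isin([0, 1]).all():
                    raise ValueError(f"binary trait {trait!r} has values outside {{0,1}}")

    def trait(self, name: str) -> pd.DataFrame:
        out = self.df[self.df["trait"] == name]
        if out.empty:
            raise KeyError(f"trait {name!r} not in table")
        return out.reset_index(drop=True)

    def per_variety_values(self, name: str) -> pd.Series:
        """Mean value per variety for one trait (collapses replicates)."""
        return self.trait(name).groupby("variety")["value"].mean()


@dataclass
class SharedMarkerMap:
    """Pairing of marker indices between two panels matched on position.

    ``pairs`` is a DataFrame with columns ``index_a, index_b, strand_flip``;
    a flip means panel B's ref/alt are swapped relative to A, so B dosage
    must be read as ``2 - dosage`` when combined with A on the same allele.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["index_a", "index_b", "strand_flip"]
        if list(self.pairs.columns[:3]) != need:
            raise ValueError(f"pairs must have columns {need}")
        self.pairs = self.pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def b_for_a(self) -> dict[int, tuple[int, bool]]:
        return {
            int(r.index_a): (int(r.index_b), bool(r.strand_flip))
            for r in self.pairs.itertuples()
        }

    def a_for_b(self) -> dict[int, tuple[int, bool]]:
        return {
            int(r.index_b): (int(r.index_a), bool(r.strand_flip))
            for r in self.pairs.itertuples()
        }

    def transpose(self) -> "SharedMarkerMap":
        out = self.pairs.rename(columns={"index_a": "index_b", "index_b": "index_a"})
        return SharedMarkerMap(out[["index_a", "index_b", "strand_flip"]])


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypePanel:
    """Load a VCF into a :class:`GenotypePanel`.

    Only biallelic records are kept; multi-allelic records are skipped with
    a logged warning.  GT is converted to alt-dosage (``./.`` becomes NaN).
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    rows, dosage_cols = [], []
    n_multi = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_multi += 1
            log.warning("skipping multi-allelic record %s:%d", var.CHROM, var.POS)
            continue
        gt = var.gt_types.astype(float)  # 0/1/2 dosage, 3 = unknown with gts012
        gt[gt == 3] = np.nan
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosage_cols.append(gt)
    vcf.close()
    if not rows:
        raise ValueError(f"{path}: no biallelic records")
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    dosages = np.column_stack(dosage_cols)
    order = markers.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    log.info("read %d markers x %d samples from %s (%d multi-allelic skipped)",
             len(rows), len(samples), path, n_multi)
    panel = GenotypePanel(markers.iloc[order], samples, dosages[:, order])
    panel.n_multiallelic_skipped = n_multi  # type: ignore[attr-defined]
    return panel


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write a panel as minimal VCFv4.2 with GT fields.

    Dosages must be integral (or missing); non-integral imputed values
    cannot be represented as genotype calls.
    """
    d = panel.dosages
    finite = d[~np.isnan(d)]
    if not np.allclose(finite, np.round(finite)):
        raise ValueError("cannot write non-integral dosages as GT; write pre-imputation data")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.varieties) + "\n")
        for j, m in enumerate(panel.markers.itertuples()):
            calls = [
                "./." if np.isnan(d[i, j]) else gt_map[int(round(d[i, j]))]
                for i in range(panel.n_varieties)
            ]
            fh.write(f"{m.chrom}\t{m.pos}\t{m.id}\t{m.ref}\t{m.alt}\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# trait table TSV
# ---------------------------------------------------------------------------

def read_trait_table(path: str, trait_types: dict[str, str] | None = None) -> TraitTable:
    df = pd.read_csv(path, sep="\t", dtype={"variety": str, "trait": str, "location": str})
    log.info("read %d trait records from %s", len(df), path)
    return TraitTable(df, trait_types or {})


def write_trait_table(table: TraitTable, path: str) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# marker QC, imputation, cross-panel intersection
# ---------------------------------------------------------------------------

def qc_filter(panel: GenotypePanel, max_missing: float = 0.1,
              min_maf: float = 0.05) -> GenotypePanel:
    """Drop markers with missing rate >= ``max_missing`` or MAF < ``min_maf``.

    The missing-rate boundary is inclusive (a marker missing in exactly 10%
    of varieties is removed) while the MAF boundary is exclusive (MAF exactly
    at the floor is retained).  MAF is computed from non-missing dosages.
    """
    miss = panel.missing_rate()
    maf = panel.maf()
    keep = (miss < max_missing) & ~(maf < min_maf)
    if not keep.any():
        raise ValueError("empty panel after QC")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("QC removed %d of %d markers (missing>=%.3g or MAF<%.3g)",
                 n_drop, panel.n_markers, max_missing, min_maf)
    return panel.subset_markers(np.flatnonzero(keep))


def impute_missing(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages with the marker mean of non-missing dosages."""
    d = panel.dosages
    if not np.isnan(d).any():
        return panel
    col_mean = np.nanmean(d, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("marker with all calls missing cannot be imputed")
    out = d.copy()
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = col_mean[nan_c]
    return GenotypePanel(panel.markers.copy(), list(panel.varieties), out)


def intersect_markers(panel_a: GenotypePanel, panel_b: GenotypePanel) -> SharedMarkerMap:
    """Match markers of two panels on (chrom, pos) and allele identity.

    Alleles must match as a set: an exact ref/alt match pairs directly; a
    swapped ref/alt pairs with ``strand_flip`` set.  Same-position sites with
    incompatible alleles are counted and logged, not paired.  Only the
    markers present in both panels enter any cross-cohort comparison.
    """
    a = panel_a.markers
    b = panel_b.markers
    b_lookup: dict[tuple, list[int]] = {}
    for jb, m in enumerate(b.itertuples()):
        b_lookup.setdefault((m.chrom, m.pos), []).append(jb)
    pairs = []
    n_allele_mismatch = 0
    for ja, m in enumerate(a.itertuples()):
        for jb in b_lookup.get((m.chrom, m.pos), []):
            rb, ab = b.at[jb, "ref"], b.at[jb, "alt"]
            if (m.ref, m.alt) == (rb, ab):
                pairs.append((ja, jb, False))
            elif (m.ref, m.alt) == (ab, rb):
                pairs.append((ja, jb, True))
            else:
                n_allele_mismatch += 1
    if n_allele_mismatch:
        log.info("%d same-position sites had incompatible alleles", n_allele_mismatch)
    df = pd.DataFrame(pairs, columns=["index_a", "index_b", "strand_flip"])
    if df.empty:
        df = pd.DataFrame({"index_a": pd.Series(dtype=int),
                           "index_b": pd.Series(dtype=int),
                           "strand_flip": pd.Series(dtype=bool)})
    return SharedMarkerMap(df)
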