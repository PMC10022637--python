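"""Synthetic rice-like panels: genotypes, traits, and two-cohort scenarios.

Genotypes follow a founder-mosaic (Li–Stephens-like) model: every chromosome
copy of every individual is a mosaic of a small pool of founder haplotypes,
with the active founder switching independently between adjacent markers at
a fixed per-interval rate.  This produces the block-wise linkage
disequilibrium that the downstream mixed-model scan, SimpleM correction and
peak identity test all rely on, while staying fully deterministic under a
seed and fast enough to regenerate at test time.

Traits are layered on top of the genotypes:

* quantitative traits as a sum of per-marker allele effects plus Gaussian
  noise scaled to a requested narrow-sense heritability;
* binary traits through a liability threshold (case iff latent liability
  exceeds the empirical quantile matching the requested prevalence);
* ordinal two-locus epistatic "color" traits, where a switch locus gates
  whether any color appears and a tone locus sets its depth (scores 1-9);
* replicated legacy-style measurements with shared location-by-year offsets
  and record thinning, emulating decades of gene-bank field records.

Every simulator returns the ground truth it used (causal markers, effects,
heritability, environment offsets) so parameter-recovery tests can compare
estimates against what was actually simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import MARKER_COLUMNS, GenotypePanel, TraitTable

SIM_LOCATION = "-"  # placeholder (location, year) for single-environment records
SIM_YEAR = 0


@dataclass
class SimConfig:
    """Parameters of the founder-mosaic genotype simulator.

    ``switch_rate`` is the probability per marker interval that a haplotype
    mosaic switches to a uniformly drawn founder; ``maf_floor`` bounds the
    founder-pool allele frequency away from 0 and 1 so markers are
    polymorphic; ``inbred`` doubles a single simulated haplotype per
    individual (selfing rice varieties are near-homozygous) instead of
    combining two independent mosaics.
    """

    n_founders: int = 8
    n_individuals: int = 200
    n_chromosomes: int = 4
    markers_per_chromosome: int = 300
    chromosome_length_bp: int = 30_000_000
    switch_rate: float = 0.02
    maf_floor: float = 0.1
    missing_rate: float = 0.02
    inbred: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_individuals", "n_chromosomes",
                     "markers_per_chromosome", "chromosome_length_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ValueError("switch_rate must be in [0, 1]")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class CausalSpec:
    """One causal marker: id, per-alt-allele effect, and the trait it acts on."""

    marker_id: str
    effect: float
    trait_name: str


@dataclass
class TruthRecord:
    """Ground truth of a simulated trait, recorded exactly as simulated."""

    causal_specs: list[CausalSpec] = field(default_factory=list)
    h2_total: float = 0.0
    liability_threshold: float | None = None
    env_effects: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_total <= 1.0:
            raise ValueError("h2_total must lie in [0, 1]")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["env_effects"] = {f"{loc}|{yr}": v for (loc, yr), v in self.env_effects.items()}
        return d


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _founder_haplotypes(rng: np.random.Generator, cfg: SimConfig, m: int) -> np.ndarray:
    """Founder alleles (n_founders x m) with per-marker alt frequency >= floor."""
    p = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=m)
    return (rng.random((cfg.n_founders, m)) < p).astype(np.int8)


def _mosaic(rng: np.random.Generator, founders: np.ndarray, n_hap: int,
            switch_rate: float) -> np.ndarray:
    """Haplotypes (n_hap x m) as founder mosaics with per-interval switching."""
    n_f, m = founders.shape
    # per-segment founder choice: segment index advances at each switch
    choice = rng.integers(0, n_f, size=(n_hap, m))
    if m > 1:
        switch = rng.random((n_hap, m - 1)) < switch_rate
        seg = np.zeros((n_hap, m), dtype=np.int64)
        seg[:, 1:] = np.cumsum(switch, axis=1)
    else:
        seg = np.zeros((n_hap, 1), dtype=np.int64)
    founder_of_seg = choice  # reuse the (n_hap, m) draw indexed by segment id
    picked = founder_of_seg[np.arange(n_hap)[:, None], seg]
    return founders[picked, np.arange(m)[None, :]]


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Simulate a diploid (or doubled-haploid) panel under the mosaic model.

    Markers are evenly spaced along each chromosome; dosage is the alt-allele
    count of the two chromosome copies.  Missing calls are injected uniformly
    at random at ``config.missing_rate`` to exercise QC and imputation.
    Identical configs (including seed) give bit-identical panels.
    """
    if config.markers_per_chromosome < 2:
        raise ValueError("degenerate chromosome: need >= 2 markers per chromosome")
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    marker_frames = []
    dosage_blocks = []
    for c in range(1, config.n_chromosomes + 1):
        m = config.markers_per_chromosome
        founders = _founder_haplotypes(rng, config, m)
        if config.inbred:
            hap = _mosaic(rng, founders, n, config.switch_rate)
            dose = (2 * hap).astype(float)
        else:
            hap1 = _mosaic(rng, founders, n, config.switch_rate)
            hap2 = _mosaic(rng, founders, n, config.switch_rate)
            dose = (hap1 + hap2).astype(float)
        pos = np.linspace(1, config.chromosome_length_bp, m).round().astype(int)
        pos = np.maximum.accumulate(pos)  # guard against rounding ties at tiny lengths
        if len(np.unique(pos)) != m:
            pos = np.arange(1, m + 1) * max(config.chromosome_length_bp // (m + 1), 1)
        chrom = f"chr{c}"
        marker_frames.append(pd.DataFrame({
            "id": [f"{chrom}_{p}" for p in pos],
            "chrom": chrom, "pos": pos,
            "ref": "A", "alt": "T",
        }))
        dosage_blocks.append(dose)
    markers = pd.concat(marker_frames, ignore_index=True)[MARKER_COLUMNS]
    dosages = np.concatenate(dosage_blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    varieties = [f"var{i:04d}" for i in range(n)]
    return GenotypePanel(markers, varieties, dosages)


def _genetic_values(panel: GenotypePanel, specs: list[CausalSpec]) -> np.ndarray:
    """Sum of per-allele effects; missing dosages enter at the marker mean."""
    g = np.zeros(panel.n_varieties)
    for spec in specs:
        j = panel.marker_index(spec.marker_id)
        x = panel.dosages[:, j]
        if np.nanstd(x) == 0:
            raise ValueError(f"no genetic variance: causal marker {spec.marker_id} monomorphic")
        x = np.where(np.isnan(x), np.nanmean(x), x)
        g = g + spec.effect * x
    return g


def _single_env_table(panel: GenotypePanel, values: np.ndarray, trait_name: str,
                      trait_type: str) -> TraitTable:
    df = pd.DataFrame({
        "variety": panel.varieties,
        "trait": trait_name,
        "location": SIM_LOCATION,
        "year": SIM_YEAR,
        "value": values,
    })
    return TraitTable(df, {trait_name: trait_type})


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_trait_quantitative(panel: GenotypePanel, specs: list[CausalSpec],
                                h2_total: float, seed: int,
                                trait_name: str | None = None,
                                ) -> tuple[TraitTable, TruthRecord]:
    """Additive quantitative trait at a requested narrow-sense heritability.

    Residual noise variance is set from the realized genetic variance so
    that Var(g)/Var(y) equals ``h2_total`` in expectation; ``h2_total = 1``
    returns the genetic values verbatim.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if not 0.0 <= h2_total <= 1.0:
        raise ValueError("h2_total must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    name = trait_name or specs[0].trait_name
    g = _genetic_values(panel, specs)
    var_g = float(np.var(g))
    if var_g == 0:
        raise ValueError("no genetic variance")
    if h2_total == 1.0:
        y = g.copy()
    else:
        if h2_total == 0.0:
            raise ValueError("h2_total = 0 leaves no genetic signal; simulate noise directly")
        sd_e = np.sqrt(var_g * (1.0 - h2_total) / h2_total)
        y = g + rng.normal(0.0, sd_e, size=len(g))
    truth = TruthRecord(causal_specs=list(specs), h2_total=h2_total)
    return _single_env_table(panel, y, name, "quantitative"), truth


def simulate_trait_binary(panel: GenotypePanel, specs: list[CausalSpec],
                          h2_liability: float, prevalence: float, seed: int,
                          trait_name: str | None = None,
                          ) -> tuple[TraitTable, TruthRecord]:
    """Binary trait from a liability threshold.

    A latent liability is simulated like a quantitative trait at
    ``h2_liability``; cases are varieties whose liability exceeds the
    empirical (1 - prevalence)-quantile, so realized prevalence matches the
    request in every sample rather than only in expectation.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    name = trait_name or (specs[0].trait_name if specs else "binary_trait")
    if specs and h2_liability > 0:
        g = _genetic_values(panel, specs)
        var_g = float(np.var(g))
        if var_g == 0:
            raise ValueError("no genetic variance")
        if h2_liability == 1.0:
            liab = g.astype(float)
        else:
            sd_e = np.sqrt(var_g * (1.0 - h2_liability) / h2_liability)
            liab = g + rng.normal(0.0, sd_e, size=len(g))
    else:
        liab = rng.normal(size=panel.n_varieties)
    tau = float(np.quantile(liab, 1.0 - prevalence))
    y = (liab > tau).astype(float)
    if y.min() == y.max():
        raise ValueError("degenerate binary trait: all cases or all controls")
    truth = TruthRecord(causal_specs=list(specs), h2_total=h2_liability,
                        liability_threshold=tau)
    return _single_env_table(panel, y, name, "binary"), truth


def simulate_legacy_replicates(trait: TraitTable, env_sd: float,
                               n_locations: int, n_years: int, seed: int,
                               residual_sd: float = 1.0,
                               keep_fraction: float = 0.8,
                               ) -> tuple[TraitTable, TruthRecord]:
    """Expand one-record-per-variety values into multi-environment records.

    Each (location, year) gets one Gaussian offset (sd ``env_sd``) shared by
    every variety measured there; each emitted record adds independent
    residual noise (sd ``residual_sd``); records are randomly thinned,
    keeping each with probability ``keep_fraction``, to mimic the ragged
    coverage of decades of gene-bank field data.  The environment offsets
    are returned in the :class:`TruthRecord`.
    """
    if n_locations * n_years == 0:
        raise ValueError("need at least one (location, year) environment")
    counts = trait.df.groupby(["variety", "trait"]).size()
    if (counts > 1).any():
        raise ValueError("input must have one record per variety")
    rng = np.random.default_rng(seed)
    locs = [f"loc{i:02d}" for i in range(1, n_locations + 1)]
    years = list(range(2001, 2001 + n_years))
    env_effects = {(loc, yr): float(rng.normal(0.0, env_sd))
                   for loc in locs for yr in years}
    rows = []
    base = trait.df
    for rec in base.itertuples():
        for loc in locs:
            for yr in years:
                if rng.random() > keep_fraction:
                    continue
                val = rec.value + env_effects[(loc, yr)] + rng.normal(0.0, residual_sd)
                rows.append((rec.variety, rec.trait, loc, yr, val))
    if not rows:
        raise ValueError("thinning removed every record; increase keep_fraction")
    df = pd.DataFrame(rows, columns=["variety", "trait", "location", "year", "value"])
    types = {t: "quantitative" for t in df["trait"].unique()}
    truth = TruthRecord(env_effects=env_effects)
    return TraitTable(df, types), truth


# ---------------------------------------------------------------------------
# two-cohort scenarios
# ---------------------------------------------------------------------------

SCENARIOS = ("shared_qtl", "distinct_qtl", "null")


def _pick_causal_marker(pool: GenotypePanel, chrom: str,
                        variety_sets: list[list[str]],
                        min_maf: float = 0.15) -> str:
    """Marker near the chromosome middle that segregates in every panel.

    Candidates are ordered by distance from the chromosome midpoint; the
    first with MAF >= ``min_maf`` in each variety subset wins (the MAF bar
    is halved until a candidate qualifies, so a causal marker always
    exists).
    """
    sub = pool.markers[pool.markers["chrom"] == chrom]
    mid_pos = sub["pos"].iloc[len(sub) // 2]
    order = (sub["pos"] - mid_pos).abs().sort_values(kind="stable").index
    row_sets = []
    pos_of = {v: i for i, v in enumerate(pool.varieties)}
    for names in variety_sets:
        row_sets.append(np.array([pos_of[v] for v in names]))
    bar = min_maf
    while bar > 1e-3:
        for j in order:
            ok = True
            for rows in row_sets:
                x = pool.dosages[rows, j]
                p = np.nanmean(x) / 2.0
                if not np.isfinite(p) or min(p, 1 - p) < bar:
                    ok = False
                    break
            if ok:
                return str(pool.markers.at[j, "id"])
        bar /= 2.0
    raise ValueError(f"no polymorphic marker on {chrom} in all panels")


def simulate_two_panels(config: SimConfig, scenario: str,
                        overlap_varieties: float = 0.5,
                        overlap_markers: float = 0.7,
                        seed: int | None = None,
                        h2_qtl: float = 0.3,
                        ) -> tuple[GenotypePanel, TraitTable, GenotypePanel, TraitTable, TruthRecord]:
    """Two partially overlapping cohorts from one founder pool.

    ``config.n_individuals`` is the size of each panel; a fraction
    ``overlap_varieties`` of them (same genotypes, same labels) appears in
    both.  Each panel genotypes a random marker subset such that a fraction
    ``overlap_markers`` of the full marker set is present in both; causal
    markers are always force-retained in both subsets so the cross-cohort
    conditioning step is well defined.

    Scenarios: ``shared_qtl`` plants the same causal marker and effect in
    both panels' traits; ``distinct_qtl`` plants causal markers on different
    chromosomes; ``null`` simulates pure-noise traits.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if not (0.0 <= overlap_varieties <= 1.0 and 0.0 <= overlap_markers <= 1.0):
        raise ValueError("overlap fractions must lie in [0, 1]")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    n = config.n_individuals
    n_shared = int(round(overlap_varieties * n))
    n_total = 2 * n - n_shared
    pool_cfg = SimConfig(**{**asdict(config), "n_individuals": n_total,
                            "seed": int(rng.integers(2**31 - 1))})
    pool = simulate_genotypes(pool_cfg)
    vars_a = pool.varieties[:n]
    vars_b = pool.varieties[n - n_shared:]

    # causal markers (on the full marker set, forced into both subsets)
    if config.n_chromosomes < 2 and scenario == "distinct_qtl":
        raise ValueError("distinct_qtl needs >= 2 chromosomes")
    causal_a: list[CausalSpec] = []
    causal_b: list[CausalSpec] = []
    if scenario == "shared_qtl":
        mid = _pick_causal_marker(pool, "chr1", [vars_a, vars_b])
        causal_a = [CausalSpec(mid, 1.0, "trait_a")]
        causal_b = [CausalSpec(mid, 1.0, "trait_b")]
    elif scenario == "distinct_qtl":
        causal_a = [CausalSpec(_pick_causal_marker(pool, "chr1", [vars_a]), 1.0, "trait_a")]
        causal_b = [CausalSpec(_pick_causal_marker(pool, "chr2", [vars_b]), 1.0, "trait_b")]

    # marker subsets: shared block plus disjoint panel-private remainders
    m = pool.n_markers
    forced = {pool.marker_index(s.marker_id) for s in causal_a + causal_b}
    perm = rng.permutation(m)
    n_shared_m = int(round(overlap_markers * m))
    shared_set = set(perm[:n_shared_m]) | forced
    rest = [j for j in perm[n_shared_m:] if j not in forced]
    half = len(rest) // 2
    idx_a = sorted(shared_set | set(rest[:half]))
    idx_b = sorted(shared_set | set(rest[half:]))

    panel_a = pool.subset_markers(idx_a).subset_varieties(vars_a)
    panel_b = pool.subset_markers(idx_b).subset_varieties(vars_b)

    if scenario == "null":
        ya = rng.normal(size=n)
        yb = rng.normal(size=n)
        trait_a = _single_env_table(panel_a, ya, "trait_a", "quantitative")
        trait_b = _single_env_table(panel_b, yb, "trait_b", "quantitative")
        truth = TruthRecord(h2_total=0.0)
    else:
        trait_a, truth_a = simulate_trait_quantitative(
            panel_a, causal_a, h2_qtl, seed=int(rng.integers(2**31 - 1)))
        trait_b, truth_b = simulate_trait_quantitative(
            panel_b, causal_b, h2_qtl, seed=int(rng.integers(2**31 - 1)))
        truth = TruthRecord(causal_specs=truth_a.causal_specs + truth_b.causal_specs,
                            h2_total=h2_qtl)
    return panel_a, trait_a, panel_b, trait_b, truth


# ---------------------------------------------------------------------------
# epistatic ordinal color trait
# ---------------------------------------------------------------------------

def simulate_epistatic_ordinal(panel: GenotypePanel, switch_marker: str,
                               tone_marker: str, seed: int,
                               trait_name: str = "apiculus_color",
                               ) -> tuple[TraitTable, TruthRecord]:
    """Two-locus epistatic ordinal trait on a 1-9 color scale.

    The alt allele at ``switch_marker`` is the functional "color on" allele:
    varieties without it score 1 (no color).  Carriers score in 2-4 (light)
    when they lack the functional (alt) tone allele and 5-9 (dark) when they
    carry it — the switch locus gates the tone locus entirely.
    """
    js = panel.marker_index(switch_marker)
    jt = panel.marker_index(tone_marker)
    xs = panel.dosages[:, js]
    xt = panel.dosages[:, jt]
    if np.nanstd(xs) == 0:
        raise ValueError("monomorphic switch_marker")
    if np.nanstd(xt) == 0:
        raise ValueError("monomorphic tone_marker")
    rng = np.random.default_rng(seed)
    # missing calls rounded through the marker mean, then carrier = dosage >= 1
    xs = np.where(np.isnan(xs), np.nanmean(xs), xs)
    xt = np.where(np.isnan(xt), np.nanmean(xt), xt)
    carrier_s = np.round(xs) >= 1
    carrier_t = np.round(xt) >= 1
    scores = np.ones(panel.n_varieties)
    light = carrier_s & ~carrier_t
    dark = carrier_s & carrier_t
    scores[light] = rng.integers(2, 5, size=int(light.sum()))
    scores[dark] = rng.integers(5, 10, size=int(dark.sum()))
    truth = TruthRecord(causal_specs=[
        CausalSpec(switch_marker, np.nan, trait_name),
        CausalSpec(tone_marker, np.nan, trait_name),
    ], h2_total=1.0)
    return _single_env_table(panel, scores, trait_name, "quantitative"), truth
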