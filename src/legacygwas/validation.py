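"""Operating-characteristic experiments for the whole toolkit.

These are the package's built-in validation studies: each function runs a
seeded simulation through the real pipeline and returns the quantity a
method paper would report — null-scan calibration, identity-test
sensitivity/specificity, REML heritability recovery, standardized-effect
recovery, and the gain of mixed-model environment adjustment over naive
means.  The same entry points back the test suite and the reproducibility
script, so reported numbers always come from live runs.

Problem sizes default to the study conditions the experiments are defined
at (panel sizes of a few hundred varieties, a few thousand markers); the
null-calibration panels use unlinked markers (``switch_rate = 1``) because
linkage only adds variance to the genomic-control median without changing
the marginal calibration of a single-marker test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import impute_missing, intersect_markers, qc_filter
from .mixed_model_scan import (compute_kinship, inflation, reml_fit,
                               scan_binary, scan_quantitative)
from .significance import call_peaks, simple_m, thresholds
from .identity_test import identity_test_regions
from .synthetic_panel import (CausalSpec, SimConfig, simulate_genotypes,
                              simulate_legacy_replicates,
                              simulate_trait_quantitative, simulate_two_panels)
from .trait_prep import PhenotypeVector, adjust_env, standardize


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_calibration_replicate(panel_seed: int, pheno_seed: int,
                               n: int = 500, markers_per_chromosome: int = 500,
                               n_chromosomes: int = 4) -> dict:
    """One null replicate: type-I error at 0.05 and lambda_GC for both scans."""
    cfg = SimConfig(n_individuals=n, markers_per_chromosome=markers_per_chromosome,
                    n_chromosomes=n_chromosomes, switch_rate=1.0, seed=panel_seed)
    panel = impute_missing(qc_filter(simulate_genotypes(cfg)))
    kin = compute_kinship(panel)
    rng = np.random.default_rng(pheno_seed)
    yq = pd.Series(rng.normal(size=panel.n_varieties), index=panel.varieties)
    yb = pd.Series(rng.binomial(1, 0.5, panel.n_varieties).astype(float),
                   index=panel.varieties)
    sq = scan_quantitative(panel, yq, kin)
    sb = scan_binary(panel, yb, kin)
    return {
        "type1_quant": float((sq.tested()["p"] < 0.05).mean()),
        "type1_binary": float((sb.tested()["p"] < 0.05).mean()),
        "lambda_quant": inflation(sq)[0],
        "lambda_binary": inflation(sb)[0],
    }


# ---------------------------------------------------------------------------
# identity test operating characteristics
# ---------------------------------------------------------------------------

def identity_replicate(scenario: str, seed: int, n: int = 300,
                       h2_qtl: float = 0.3, overlap_markers: float = 0.7,
                       overlap_varieties: float = 0.5,
                       markers_per_chromosome: int = 500,
                       n_chromosomes: int = 4,
                       merge_gap: int = 1_000_000,
                       pad: int = 300_000,
                       swap: bool = False) -> dict:
    """One two-cohort replicate ending in an identity verdict.

    Returns the verdict for the peak region of cohort A that contains (or,
    for the null scenario, any called peak) the planted causal marker;
    ``verdict`` is "no_peak" when cohort A's scan calls no usable region.
    """
    cfg = SimConfig(n_individuals=n, markers_per_chromosome=markers_per_chromosome,
                    n_chromosomes=n_chromosomes, seed=seed)
    panel_a, trait_a, panel_b, trait_b, truth = simulate_two_panels(
        cfg, scenario, overlap_varieties=overlap_varieties,
        overlap_markers=overlap_markers, seed=seed, h2_qtl=h2_qtl)
    if swap:  # probe direction symmetry: condition cohort B on cohort A's top
        panel_a, trait_a, panel_b, trait_b = panel_b, trait_b, panel_a, trait_a
    pa = impute_missing(qc_filter(panel_a))
    pb = impute_missing(qc_filter(panel_b))
    shared = intersect_markers(pa, pb)
    ka, kb = compute_kinship(pa), compute_kinship(pb)
    ya = trait_a.per_variety_values(trait_a.df["trait"].iloc[0])
    yb = trait_b.per_variety_values(trait_b.df["trait"].iloc[0])
    sa = scan_quantitative(pa, ya, ka)
    sb = scan_quantitative(pb, yb, kb)
    thr = thresholds(simple_m(pa))
    peaks = call_peaks(sa, thr.cutoff(0.1), merge_gap=merge_gap, pad=pad)
    out = {"scenario": scenario, "seed": seed, "n_peaks_a": len(peaks),
           "verdict": "no_peak", "m1_status": None, "r_squared": None,
           "max_mlp_a": float(sa.tested()["minus_log10_p"].max()),
           "threshold_01": thr.cutoff(0.1)}
    if not peaks:
        return out
    if truth.causal_specs:
        causal_a = truth.causal_specs[0]
        ja = None
        try:
            ja = pa.marker_index(causal_a.marker_id)
        except KeyError:
            pass
        target = None
        if ja is not None:
            chrom = pa.markers.at[ja, "chrom"]
            pos = int(pa.markers.at[ja, "pos"])
            for r in peaks:
                if r.contains(chrom, pos):
                    target = r
                    break
        if target is None:  # peak called but not over the causal marker
            target = max(peaks, key=lambda r: r.top_minus_log10_p)
    else:
        target = max(peaks, key=lambda r: r.top_minus_log10_p)
    verdicts = identity_test_regions(pa, ya, ka, sa, pb, sb, shared,
                                     [target], thr)
    if not verdicts:
        return out
    v = verdicts[0]
    out.update(verdict=v.verdict, m1_status=v.method1.status,
               r_squared=v.method2.r_squared)
    return out


def identity_operating_characteristics(n_reps: int = 50, seed0: int = 0,
                                       **kwargs) -> dict:
    """Fraction of shared_qtl reps called identical and distinct_qtl called distinct."""
    shared = [identity_replicate("shared_qtl", seed0 + r, **kwargs)
              for r in range(n_reps)]
    distinct = [identity_replicate("distinct_qtl", seed0 + r, **kwargs)
                for r in range(n_reps)]
    return {
        "shared_identical_fraction":
            float(np.mean([r["verdict"] == "identical" for r in shared])),
        "distinct_distinct_fraction":
            float(np.mean([r["verdict"] == "distinct" for r in distinct])),
        "shared": shared,
        "distinct": distinct,
    }


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def h2_recovery_replicate(seed: int, n: int = 500, h2: float = 0.5,
                          markers_per_chromosome: int = 250,
                          n_chromosomes: int = 4) -> float:
    """REML heritability estimate for a polygenic trait drawn from K itself."""
    cfg = SimConfig(n_individuals=n, markers_per_chromosome=markers_per_chromosome,
                    n_chromosomes=n_chromosomes, seed=seed)
    panel = impute_missing(qc_filter(simulate_genotypes(cfg)))
    kin = compute_kinship(panel)
    rng = np.random.default_rng(seed + 10_000)
    lam, U = np.linalg.eigh(kin.K)
    lam = np.clip(lam, 0.0, None)
    g = U @ (np.sqrt(lam) * rng.normal(size=len(lam)))
    g = g / g.std()
    e = rng.normal(size=len(g))
    e = e / e.std()
    y = np.sqrt(h2) * g + np.sqrt(1 - h2) * e
    fit = reml_fit(y, np.ones((len(y), 1)), kin.K)
    return fit.heritability


def effect_recovery(n_scenarios: int = 20, seed0: int = 0, n: int = 500,
                    markers_per_chromosome: int = 200,
                    n_chromosomes: int = 2) -> pd.DataFrame:
    """Planned vs recovered standardized effect of a causal marker.

    Scenario s plants a causal marker explaining a fraction beta_s^2 of
    phenotypic variance (so the standardized per-allele effect is
    beta_s / sd(x)); the scan on the z-scored trait re-estimates it.
    """
    planned = np.linspace(0.05, 0.5, n_scenarios)
    rows = []
    for s, target in enumerate(planned):
        cfg = SimConfig(n_individuals=n,
                        markers_per_chromosome=markers_per_chromosome,
                        n_chromosomes=n_chromosomes, seed=seed0 + s)
        panel = impute_missing(qc_filter(simulate_genotypes(cfg)))
        kin = compute_kinship(panel)
        mid = panel.markers["id"].iloc[panel.n_markers // 2]
        trait, _ = simulate_trait_quantitative(
            panel, [CausalSpec(str(mid), 1.0, "t")], h2_total=float(target**2),
            seed=seed0 + 5_000 + s)
        y = trait.per_variety_values("t")
        z = standardize(PhenotypeVector(y, "t"))
        scan = scan_quantitative(panel, z.values, kin)
        x = panel.dosages[:, panel.marker_index(str(mid))]
        beta_true = target / float(np.std(x))
        row = scan.df.set_index("id").loc[str(mid)]
        rows.append((target, beta_true, abs(float(row["beta"]))))
    return pd.DataFrame(rows, columns=["planned_r", "planned_beta_sd",
                                       "recovered_abs_beta"])


# ---------------------------------------------------------------------------
# environment adjustment gain
# ---------------------------------------------------------------------------

def env_adjustment_gain(seed: int, n_varieties: int = 150, env_sd: float = 5.0,
                        n_locations: int = 6, n_years: int = 3,
                        keep_fraction: float = 0.5) -> dict:
    """Correlation with truth: mixed-model BLUEs vs naive per-variety means.

    True values are Gaussian variety effects; replicated records add shared
    location-by-year offsets, residual noise, and heavy thinning, so naive
    means are biased by each variety's environment draw.
    """
    rng = np.random.default_rng(seed)
    true_vals = rng.normal(0.0, 2.0, n_varieties)
    base = pd.DataFrame({
        "variety": [f"v{i:03d}" for i in range(n_varieties)],
        "trait": "t", "location": "-", "year": 0, "value": true_vals,
    })
    from .data_io import TraitTable
    table = TraitTable(base, {"t": "quantitative"})
    reps, truth = simulate_legacy_replicates(
        table, env_sd=env_sd, n_locations=n_locations, n_years=n_years,
        seed=seed + 1, keep_fraction=keep_fraction)
    adjusted = adjust_env(reps, "t")
    naive = reps.per_variety_values("t")
    truth_s = pd.Series(true_vals, index=base["variety"])
    common = adjusted.values.index.intersection(naive.index)
    r_adj = float(np.corrcoef(adjusted.values.loc[common], truth_s.loc[common])[0, 1])
    r_naive = float(np.corrcoef(naive.loc[common], truth_s.loc[common])[0, 1])
    return {"r_adjusted": r_adj, "r_naive": r_naive, "gain": r_adj - r_naive}
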