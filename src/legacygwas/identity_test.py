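"""The peak identity test: are two GWAS peaks the same QTL?

When two independent cohorts — one scored with legacy database phenotypes,
one with newly measured phenotypes — both show an association peak, peak
overlap alone does not establish that they tag the same causal locus.
The identity test combines two complementary checks:

* **Method 1 (conditional disappearance).**  Rerun cohort A's scan with
  the top marker of cohort B's peak included as a fixed-effect covariate.
  If the two peaks reflect the same QTL, the covariate absorbs the signal
  and A's peak drops below the lenient genome-wide threshold
  ("disappeared"); a large but incomplete drop is "attenuated", anything
  else "persisted".
* **Method 2 (signal-shape correlation).**  Over the markers tested in
  both cohorts inside the peak region, correlate the two -log10(p)
  profiles; R^2 of that correlation measures whether the local association
  landscape is the same.

``combine`` turns the pair of outcomes into a verdict: identical
(disappeared + high R^2), partially shared (attenuated + high R^2, the
signature of an extra local QTL in one cohort), distinct (persisted + low
R^2), or inconclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypePanel, SharedMarkerMap
from .mixed_model_scan import KinshipMatrix, ScanResult, conditional_scan, scan_quantitative
from .significance import PeakRegion, ThresholdSet

log = logging.getLogger(__name__)

PROXY_MIN_ABS_R = 0.8  # weakest acceptable stand-in for an unshared top marker


@dataclass
class Method1Outcome:
    region: PeakRegion
    conditioning_marker: str
    unconditional_max: float
    conditional_max: float
    status: str  # disappeared | attenuated | persisted


@dataclass
class Method2Outcome:
    region: PeakRegion
    n_shared: int
    r_squared: float
    pairs: pd.DataFrame  # columns: id, pos, mlp_a, mlp_b


@dataclass
class IdentityVerdict:
    method1: Method1Outcome
    method2: Method2Outcome
    verdict: str  # identical | partially_shared | distinct | inconclusive


# ---------------------------------------------------------------------------

def _region_mask(df: pd.DataFrame, region: PeakRegion) -> pd.Series:
    return ((df["chrom"] == region.chrom)
            & (df["pos"] >= region.start) & (df["pos"] < region.end))


def resolve_conditioning_marker(top_marker_b: str, panel_a: GenotypePanel,
                                panel_b: GenotypePanel,
                                shared_map: SharedMarkerMap) -> str:
    """Map cohort B's top marker into panel A, falling back to a proxy.

    If the marker itself is shared, return its panel-A id.  Otherwise pick
    the shared marker with the highest |r| to it within panel B; |r| below
    0.8 is refused (conditioning on a weak proxy would not absorb the
    signal and would bias the verdict toward "persisted").
    """
    jb = panel_b.marker_index(top_marker_b)
    a_for_b = shared_map.a_for_b()
    if jb in a_for_b:
        ja, _ = a_for_b[jb]
        return str(panel_a.markers.at[ja, "id"])
    x = panel_b.dosages[:, jb]
    x = np.where(np.isnan(x), np.nanmean(x), x)
    best_r, best_ja = 0.0, None
    for jb_shared, (ja, _flip) in a_for_b.items():
        z = panel_b.dosages[:, jb_shared]
        z = np.where(np.isnan(z), np.nanmean(z), z)
        if z.std() == 0 or x.std() == 0:
            continue
        r = abs(float(np.corrcoef(x, z)[0, 1]))
        if r > best_r:
            best_r, best_ja = r, ja
    if best_ja is None or best_r < PROXY_MIN_ABS_R:
        raise ValueError(
            f"conditioning marker not shared: {top_marker_b} has no proxy with "
            f"|r| >= {PROXY_MIN_ABS_R} among shared markers (best {best_r:.2f})")
    proxy = str(panel_a.markers.at[best_ja, "id"])
    log.info("top marker %s not shared; conditioning on proxy %s (|r|=%.3f)",
             top_marker_b, proxy, best_r)
    return proxy


def method1(panel_a: GenotypePanel, y_a: pd.Series, kinship_a: KinshipMatrix,
            region: PeakRegion, top_marker_b: str, shared_map: SharedMarkerMap,
            threshold_set: ThresholdSet, panel_b: GenotypePanel | None = None,
            scan_a: ScanResult | None = None,
            attenuation_fraction: float = 0.5,
            lenient_alpha: float = 0.2) -> Method1Outcome:
    """Conditional-disappearance test of cohort A's peak on B's top marker.

    ``top_marker_b`` is an id in panel B's marker table (mapped through the
    shared-marker map; an unshared top marker falls back to its best shared
    proxy when ``panel_b`` is given) or, if it already names a panel-A
    marker, used directly.  Status is judged against the lenient
    (alpha = 0.2) genome-wide cutoff: below it the peak "disappeared";
    at or above it but with the peak height dropping by at least
    ``attenuation_fraction`` of its unconditional value, "attenuated";
    otherwise "persisted".
    """
    try:
        cond_id = str(panel_a.markers.at[panel_a.marker_index(top_marker_b), "id"])
    except KeyError:
        if panel_b is None:
            raise ValueError(f"conditioning marker not shared: {top_marker_b}")
        cond_id = resolve_conditioning_marker(top_marker_b, panel_a, panel_b, shared_map)

    if scan_a is None:
        scan_a = scan_quantitative(panel_a, y_a, kinship_a)
    in_region = _region_mask(scan_a.df, region) & (scan_a.df["excluded_reason"] == "")
    if not in_region.any():
        raise ValueError("empty region: no tested panel-A markers inside the peak")
    unconditional_max = float(scan_a.df.loc[in_region, "minus_log10_p"].max())

    cond_scan = conditional_scan(panel_a, y_a, kinship_a, [cond_id])
    cdf = cond_scan.df
    c_region = _region_mask(cdf, region) & (cdf["excluded_reason"] == "")
    if c_region.any():
        conditional_max = float(cdf.loc[c_region, "minus_log10_p"].max())
    else:
        # every region marker is a perfect proxy of the conditioning marker:
        # the covariate absorbs the region's signal completely
        conditional_max = 0.0

    cutoff = threshold_set.cutoff(lenient_alpha)
    if conditional_max < cutoff:
        status = "disappeared"
    elif unconditional_max - conditional_max >= attenuation_fraction * unconditional_max:
        status = "attenuated"
    else:
        status = "persisted"
    return Method1Outcome(region=region, conditioning_marker=cond_id,
                          unconditional_max=unconditional_max,
                          conditional_max=conditional_max, status=status)


def method2(scan_a: ScanResult, scan_b: ScanResult, region: PeakRegion,
            shared_map: SharedMarkerMap) -> Method2Outcome:
    """Correlation of the two cohorts' -log10(p) profiles inside the region.

    Only markers present and tested in both scans enter; R^2 is the square
    of the Pearson correlation of the paired -log10(p) values.
    """
    da, db = scan_a.df, scan_b.df
    rows = []
    for rec in shared_map.pairs.itertuples():
        ra = da.iloc[int(rec.index_a)]
        rb = db.iloc[int(rec.index_b)]
        if not region.contains(str(ra["chrom"]), int(ra["pos"])):
            continue
        if ra["excluded_reason"] != "" or rb["excluded_reason"] != "":
            continue
        rows.append((ra["id"], int(ra["pos"]),
                     float(ra["minus_log10_p"]), float(rb["minus_log10_p"])))
    pairs = pd.DataFrame(rows, columns=["id", "pos", "mlp_a", "mlp_b"])
    n_shared = len(pairs)
    if n_shared < 3:
        raise ValueError(f"insufficient shared markers in region (n_shared={n_shared})")
    if pairs["mlp_a"].std() == 0 or pairs["mlp_b"].std() == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(pairs["mlp_a"], pairs["mlp_b"])[0, 1] ** 2)
    return Method2Outcome(region=region, n_shared=n_shared, r_squared=r2, pairs=pairs)


def combine(m1: Method1Outcome, m2: Method2Outcome,
            r2_min: float = 0.4) -> IdentityVerdict:
    """Combine the two outcomes into a verdict.

    identical: disappeared and R^2 >= r2_min; partially_shared: attenuated
    and R^2 >= r2_min (same QTL plus evidence of an extra local signal in
    cohort A); distinct: persisted and R^2 < r2_min; inconclusive otherwise.
    The default r2_min of 0.4 is the weakest local signal-shape agreement
    still treated as sharing.
    """
    if (m1.region.chrom, m1.region.start, m1.region.end) != \
            (m2.region.chrom, m2.region.start, m2.region.end):
        raise ValueError("method 1 and method 2 refer to different regions")
    high = m2.r_squared >= r2_min
    if m1.status == "disappeared" and high:
        verdict = "identical"
    elif m1.status == "attenuated" and high:
        verdict = "partially_shared"
    elif m1.status == "persisted" and not high:
        verdict = "distinct"
    else:
        verdict = "inconclusive"
    return IdentityVerdict(method1=m1, method2=m2, verdict=verdict)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def identity_test_regions(panel_a: GenotypePanel, y_a: pd.Series,
                          kinship_a: KinshipMatrix, scan_a: ScanResult,
                          panel_b: GenotypePanel, scan_b: ScanResult,
                          shared_map: SharedMarkerMap,
                          regions: list[PeakRegion],
                          threshold_set: ThresholdSet,
                          r2_min: float = 0.4) -> list[IdentityVerdict]:
    """Run the full identity test on each candidate region.

    Method 1 conditions cohort A's scan on cohort B's genome-wide top
    marker (the strongest signal in the other study, mapped through the
    shared-marker map or its best shared proxy); Method 2 correlates the
    two scans' -log10 p profiles inside each region.
    """
    verdicts = []
    top_b_id = str(scan_b.top_marker()["id"])
    for region in regions:
        try:
            m1 = method1(panel_a, y_a, kinship_a, region, top_b_id, shared_map,
                         threshold_set, panel_b=panel_b, scan_a=scan_a)
        except ValueError as exc:
            log.warning("method 1 unavailable for %s:%d-%d (%s); region skipped",
                        region.chrom, region.start, region.end, exc)
            continue
        try:
            m2 = method2(scan_a, scan_b, region, shared_map)
        except ValueError as exc:
            log.warning("method 2 unavailable for %s:%d-%d (%s); verdict inconclusive",
                        region.chrom, region.start, region.end, exc)
            m2 = Method2Outcome(region=region, n_shared=0, r_squared=float("nan"),
                                pairs=pd.DataFrame(columns=["id", "pos", "mlp_a", "mlp_b"]))
            verdicts.append(IdentityVerdict(method1=m1, method2=m2,
                                            verdict="inconclusive"))
            continue
        verdicts.append(combine(m1, m2, r2_min=r2_min))
    return verdicts
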