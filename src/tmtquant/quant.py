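"""TMT reporter-ion quantification: PSM filtering, ratio conversion,
outlier removal, protein roll-up, MAD normalization and plex integration.

The quantification model follows the TMT-Integrator scheme.  Reporter
intensities are converted to log2 ratios against the pooled-reference
channel, rolled up to protein (or gene) medians after interquartile-range
outlier trimming, and normalized per sample by median centering and median
absolute deviation (MAD) scaling: with ratios ``R_ij`` (protein i, sample j,
rows = proteins throughout),

    M_j    = median_i(R_ij)
    Rc_ij  = R_ij - M_j
    MAD_j  = median_i(|Rc_ij|)
    MAD_0  = median_j(MAD_j)
    Rn_ij  = (Rc_ij / MAD_j) * MAD_0

Normalized ratios are converted back to the absolute log2 intensity scale
via each protein's estimated reference intensity (top-3 summed MS1):
``A_ij = Rn_ij + log2(REF_i)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CONTAMINANT_PREFIX, REFERENCE_CHANNEL, REPORTER_COLUMNS

#: rejection order used for the first-failing-criterion report
FILTER_ORDER = ("reference", "probability", "purity", "ms1", "ms2", "contaminant")


@dataclass
class FilterCriteria:
    """PSM quality thresholds.

    ``min_ms1_intensity_percentile`` is read as a fraction of the largest
    MS1 intensity in the plex (a percentage threshold needs a scale-free
    reference); ``min_ms2_fraction`` as a fraction of the per-plex median
    summed reporter intensity.
    """

    min_peptide_probability: float = 0.9
    min_precursor_purity: float = 0.5
    min_ms1_intensity_percentile: float = 0.0005
    min_ms2_fraction: float = 0.05
    require_reference_quantified: bool = True
    exclude_contaminants: bool = True
    contaminant_prefix: str = CONTAMINANT_PREFIX

    def validate(self) -> None:
        for name in ("min_peptide_probability", "min_precursor_purity",
                     "min_ms1_intensity_percentile", "min_ms2_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1], got {v}")


def filter_psms(psms: pd.DataFrame, criteria: FilterCriteria | None = None,
                reference_channel: str = REFERENCE_CHANNEL):
    """Keep PSMs passing all criteria; return ``(kept, report)``.

    ``report`` counts rejections by the first failing criterion, in the
    documented order: reference, probability, purity, MS1, MS2, contaminant.
    Input order is preserved.
    """
    criteria = criteria or FilterCriteria()
    criteria.validate()
    if reference_channel not in REPORTER_COLUMNS:
        raise ValueError(f"unknown reference channel: {reference_channel}")
    report = {k: 0 for k in FILTER_ORDER}
    if len(psms) == 0:
        report["kept"] = 0
        return psms.copy(), report

    ref = psms[reference_channel].astype(float)
    fails = {
        "reference": (ref.isna() | (ref <= 0)).values
        if criteria.require_reference_quantified
        else np.zeros(len(psms), bool),
        "probability":
            (psms["peptide_probability"] < criteria.min_peptide_probability).values,
        "purity":
            (psms["precursor_purity"] < criteria.min_precursor_purity).values,
        "ms1": (psms["ms1_intensity"]
                < criteria.min_ms1_intensity_percentile
                * psms["ms1_intensity"].max()).values,
        "ms2": (psms["ms2_summed_intensity"]
                < criteria.min_ms2_fraction
                * psms["ms2_summed_intensity"].median()).values,
        "contaminant":
            psms["protein"].str.startswith(criteria.contaminant_prefix).values
            if criteria.exclude_contaminants else np.zeros(len(psms), bool),
    }
    rejected = np.zeros(len(psms), bool)
    for name in FILTER_ORDER:
        first_fail = fails[name] & ~rejected
        report[name] = int(first_fail.sum())
        rejected |= fails[name]
    kept = psms.loc[~rejected].copy()
    report["kept"] = len(kept)
    return kept, report


def deduplicate_psms(psms: pd.DataFrame) -> pd.DataFrame:
    """Among PSMs sharing a spectrum_id keep the one with the highest summed
    TMT intensity; ties go to the first occurrence.  Order preserved."""
    if len(psms) == 0:
        return psms.copy()
    work = psms.reset_index(drop=True)
    sums = work["ms2_summed_intensity"].astype(float)
    winners = work.groupby("spectrum_id", sort=False).apply(
        lambda g: g.index[np.argmax(sums.loc[g.index].values)],
        include_groups=False,
    )
    keep = np.sort(winners.values)
    return psms.iloc[keep].copy()


def to_log_ratios(psms: pd.DataFrame, design: pd.DataFrame,
                  pooled_reference: bool = False) -> pd.DataFrame:
    """Convert reporter intensities to per-PSM log2 ratios to the reference.

    The reference is the channel flagged ``is_reference`` in the design; with
    ``pooled_reference=True`` (single-plex cohorts without a master mix) the
    per-PSM mean of all log2 channel intensities is used instead and every
    design channel yields a ratio.  Missing reporters give missing ratios.
    """
    channels = list(design["channel"])
    sample_of = dict(zip(design["channel"], design["sample_id"]))
    rep = psms[channels].astype(float)
    bad = (rep <= 0).any(axis=1)
    if bad.any():
        first = psms.loc[bad.idxmax(), "spectrum_id"]
        raise ValueError(
            f"non-positive reporter intensity in record {first!r}"
        )
    log2rep = np.log2(rep)
    if pooled_reference:
        ref_log2 = log2rep.mean(axis=1, skipna=True)
        sample_channels = channels
    else:
        is_ref = design["is_reference"].astype(bool)
        if is_ref.sum() != 1:
            raise ValueError("design must flag exactly one reference channel")
        ref_channel = design.loc[is_ref, "channel"].iloc[0]
        ref_log2 = log2rep[ref_channel]
        sample_channels = [c for c in channels if c != ref_channel]
    out = pd.DataFrame({
        "spectrum_id": psms["spectrum_id"].values,
        "protein": psms["protein"].values,
        "gene": psms["gene"].values,
    })
    for c in sample_channels:
        out[sample_of[c]] = (log2rep[c] - ref_log2).values
    return out


def remove_outliers_iqr(values, k: float = 1.5, min_group: int = 4) -> np.ndarray:
    """Drop values outside ``[Q1 - k*IQR, Q3 + k*IQR]``.

    Applied only when there are at least ``min_group`` values (quartiles of
    fewer points over-trim); quartiles use linear interpolation.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < min_group:
        return arr
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    return arr[(arr >= q1 - k * iqr) & (arr <= q3 + k * iqr)]


def rollup(ratios: pd.DataFrame, by: str = "gene", outlier_k: float = 1.5,
           min_group: int = 4, sample_order=None) -> pd.DataFrame:
    """Roll per-PSM ratios up to a proteins x samples median matrix.

    Within each (entry, sample) group, IQR outlier trimming is applied once
    (when the group has >= ``min_group`` values), then the median is taken.
    Cells with no surviving PSM are missing.
    """
    if by not in ("gene", "protein"):
        raise ValueError("by: must be 'gene' or 'protein'")
    meta = {"spectrum_id", "protein", "gene"}
    sample_cols = [c for c in ratios.columns if c not in meta]
    long = ratios.melt(id_vars=[by], value_vars=sample_cols,
                       var_name="sample", value_name="ratio").dropna(
                           subset=["ratio"])
    if len(long) == 0:
        return pd.DataFrame(columns=sample_cols)
    g = long.groupby([by, "sample"], sort=False)["ratio"]
    q = g.quantile([0.25, 0.75]).unstack()
    stats = pd.DataFrame({"q1": q[0.25], "q3": q[0.75], "n": g.size()})
    stats["lo"] = stats["q1"] - outlier_k * (stats["q3"] - stats["q1"])
    stats["hi"] = stats["q3"] + outlier_k * (stats["q3"] - stats["q1"])
    long = long.join(stats, on=[by, "sample"])
    keep = (long["n"] < min_group) | (
        (long["ratio"] >= long["lo"]) & (long["ratio"] <= long["hi"]))
    mat = (long[keep].groupby([by, "sample"], sort=False)["ratio"]
           .median().unstack("sample"))
    mat = mat.sort_index()
    cols = sample_order if sample_order is not None else sample_cols
    return mat.reindex(columns=list(cols))


@dataclass
class MadNormalized:
    """MAD-normalized ratio matrix with its per-sample statistics."""

    ratios: pd.DataFrame
    sample_median: pd.Series   # M_j
    sample_mad: pd.Series      # MAD_j (of centered values)
    global_mad: float          # MAD_0


def mad_normalize(matrix: pd.DataFrame) -> MadNormalized:
    """Median-center and MAD-scale each sample (column) of a ratio matrix.

    Implements exactly, per sample over non-missing entries: subtract the
    sample median, compute the sample MAD of the centered values, and scale
    by ``MAD_0 / MAD_j`` where ``MAD_0`` is the median of the sample MADs.
    Samples whose values are all equal (MAD 0) are returned centered but
    unscaled, with a warning.  Missing cells stay missing.
    """
    med = matrix.median(axis=0, skipna=True)
    centered = matrix.sub(med, axis=1)
    mad = centered.abs().median(axis=0, skipna=True)
    mad0 = float(mad.median(skipna=True))
    scaled = centered.copy()
    zero = (mad == 0) | mad.isna()
    if zero.any():
        warnings.warn(
            f"samples with zero MAD left unscaled: {list(mad.index[zero])}")
    if mad0 > 0:
        ok = ~zero
        scaled.loc[:, ok] = centered.loc[:, ok].div(mad[ok], axis=1) * mad0
    return MadNormalized(scaled, med, mad, mad0)


@dataclass
class ReferenceIntensity:
    """Per-protein reference-sample intensity estimates."""

    per_plex: pd.DataFrame   # proteins x plexes, REF_ik (NaN where absent)
    combined: pd.Series      # REF_i, absent plexes imputed by the global minimum
    global_min: float


def estimate_reference_intensity(psm_tables: list, by: str = "gene",
                                 plex_ids=None, top_n: int = 3,
                                 weights=None) -> ReferenceIntensity:
    """Estimate each protein's reference intensity from MS1 precursor signal.

    ``REF_ik`` is the weighted sum of the ``top_n`` most intense MS1
    precursors of protein i in plex k (all of them when fewer; weights
    default to 1, applied in descending-intensity order).  ``REF_i`` is the
    mean over plexes, with absent plexes imputed by the global minimum
    ``REF_ik`` over all proteins and plexes.
    """
    if plex_ids is None:
        plex_ids = [f"plex{k + 1}" for k in range(len(psm_tables))]
    w = np.ones(top_n) if weights is None else np.asarray(weights, float)
    if len(w) != top_n:
        raise ValueError("weights: need one weight per summed peptide ion")

    def top_sum(s: pd.Series) -> float:
        vals = np.sort(s.values)[::-1][:top_n]
        return float(np.sum(vals * w[:len(vals)]))

    per_plex = {}
    for pid, table in zip(plex_ids, psm_tables):
        per_plex[pid] = table.groupby(by)["ms1_intensity"].agg(top_sum)
    frame = pd.DataFrame(per_plex).sort_index()
    empty = frame.isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"proteins with no PSM in any plex excluded: {list(frame.index[empty])}")
        frame = frame.loc[~empty]
    global_min = float(np.nanmin(frame.values))
    combined = frame.fillna(global_min).mean(axis=1)
    return ReferenceIntensity(frame, combined, global_min)


def to_abundance(norm_ratios: pd.DataFrame, ref: pd.Series | ReferenceIntensity
                 ) -> pd.DataFrame:
    """Back-convert normalized ratios to log2 abundances:
    ``A_ij = Rn_ij + log2(REF_i)``."""
    if isinstance(ref, ReferenceIntensity):
        ref = ref.combined
    missing = norm_ratios.index.difference(ref.index)
    if len(missing) > 0:
        raise ValueError(
            f"no reference intensity for proteins: {list(missing)}")
    return norm_ratios.add(np.log2(ref.reindex(norm_ratios.index)), axis=0)


def integrate_plexes(matrices: list, plex_ids=None):
    """Concatenate per-plex proteins x samples matrices column-wise.

    Rows are the union of protein sets (missing cells where a protein was
    not seen in a plex).  Returns ``(combined, sample_plex)`` where
    ``sample_plex`` records each column's plex of origin.
    """
    if plex_ids is None:
        plex_ids = [f"plex{k + 1}" for k in range(len(matrices))]
    seen: dict = {}
    for pid, m in zip(plex_ids, matrices):
        for s in m.columns:
            if s in seen:
                raise ValueError(
                    f"duplicate sample id {s!r} in {seen[s]} and {pid}")
            seen[s] = pid
    all_rows = sorted(set().union(*[set(m.index) for m in matrices]))
    combined = pd.concat(
        [m.reindex(index=all_rows) for m in matrices], axis=1)
    sample_plex = pd.Series({s: p for s, p in seen.items()},
                            name="plex")[combined.columns]
    return combined, sample_plex


@dataclass
class QuantResult:
    """Output of the per-cohort quantification pipeline."""

    abundance: pd.DataFrame          # proteins x samples, log2 scale
    normalized: MadNormalized
    ratio_matrix: pd.DataFrame       # combined pre-normalization ratios
    reference: ReferenceIntensity
    sample_plex: pd.Series
    filter_reports: list
    kept_psms: list = field(repr=False, default=None)


def quantify_cohort(psm_tables: list, designs: list,
                    criteria: FilterCriteria | None = None, by: str = "gene",
                    pooled_reference: bool = False,
                    outlier_k: float = 1.5) -> QuantResult:
    """Run filter -> dedup -> ratios -> roll-up per plex, then integrate,
    MAD-normalize across all samples and back-convert to abundances."""
    criteria = criteria or FilterCriteria()
    plex_ids, mats, reports, kept_all = [], [], [], []
    for table, design in zip(psm_tables, designs):
        pid = design["plex_id"].iloc[0]
        plex_ids.append(pid)
        ref_rows = design.loc[design["is_reference"].astype(bool), "channel"]
        ref_channel = ref_rows.iloc[0] if len(ref_rows) else REFERENCE_CHANNEL
        kept, report = filter_psms(table, criteria, reference_channel=ref_channel)
        kept = deduplicate_psms(kept)
        ratios = to_log_ratios(kept, design, pooled_reference=pooled_reference)
        mats.append(rollup(ratios, by=by, outlier_k=outlier_k))
        reports.append(report)
        kept_all.append(kept)
    combined, sample_plex = integrate_plexes(mats, plex_ids)
    norm = mad_normalize(combined)
    ref = estimate_reference_intensity(kept_all, by=by, plex_ids=plex_ids)
    abundance = to_abundance(norm.ratios, ref)
    return QuantResult(abundance, norm, combined, ref, sample_plex,
                       reports, kept_all)
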