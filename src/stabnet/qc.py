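"""QC-based feature filtering applied to the deconvolved feature table.

Three filters, in order, after zero-to-missing conversion:

1. dilution response — a genuine analyte scales with the QC dilution-series
   concentration; features whose intensity is not positively and strongly
   (r^2 > 0.5) correlated with the relative concentration are background.
2. QC repeatability — features with %CV > 30 over the repeated undiluted
   QC injections are analytically unreliable.
3. missingness — features missing in more than 20% of quantified
   (study + qc) samples are dropped.

Each stage consumes the previous stage's retained set; the composite report
records the chain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FeatureTable, FilterRecord, FilterReport


def zeros_to_missing(table: FeatureTable) -> FeatureTable:
    """Replace exact-zero intensities with missing (NaN); all else unchanged."""
    intens = table.intensities.copy()
    vals = intens.to_numpy(dtype=float)
    vals[vals == 0.0] = np.nan
    return FeatureTable(
        intensities=pd.DataFrame(vals, index=intens.index, columns=intens.columns),
        samples=table.samples.copy(),
        features=table.features.copy(),
    )


def _pairwise_r(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pearson r over pairwise-complete observations; returns (r, n_used)."""
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return np.nan, n
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(ddof=1), ys.std(ddof=1)
    if sx == 0 or sy == 0:
        return 0.0, n
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r, n


def filter_dilution_response(
    table: FeatureTable, r2_threshold: float = 0.5
) -> FilterReport:
    """Retain features responding to the QC dilution series.

    A feature is retained iff the squared Pearson correlation between its
    intensity and the relative concentration over the qc_dilution samples
    exceeds ``r2_threshold`` *and* the correlation is positive (intensity
    increasing with concentration). Features with fewer than 3 usable
    dilution points are removed conservatively.
    """
    dil_ids = table.sample_ids("qc_dilution")
    if len(dil_ids) < 3 or table.samples.loc[dil_ids, "dilution_factor"].nunique() < 3:
        raise ValueError("need >=3 qc_dilution samples with distinct factors")
    conc = table.samples.loc[dil_ids, "dilution_factor"].to_numpy(dtype=float)
    sub = table.intensities.loc[dil_ids]
    recs = []
    for fid in table.feature_ids:
        r, n = _pairwise_r(sub[fid].to_numpy(dtype=float), conc)
        if n < 3:
            recs.append(FilterRecord(fid, "dilution", np.nan, "removed",
                                     "insufficient_dilution_data"))
            continue
        r2 = r * r
        ok = (r2 > r2_threshold) and (r > 0)
        recs.append(FilterRecord(fid, "dilution", r2,
                                 "retained" if ok else "removed"))
    return FilterReport.from_records(recs)


def filter_qc_cv(table: FeatureTable, cv_threshold: float = 30.0) -> FilterReport:
    """Retain features with %CV <= threshold over undiluted QC injections.

    %CV = 100 * sample SD (n-1) / mean, missing values dropped. The
    inequality is strict: %CV exactly at the threshold is retained.
    """
    qc_ids = table.sample_ids("qc")
    if len(qc_ids) < 2:
        raise ValueError("need >=2 qc replicate injections")
    sub = table.intensities.loc[qc_ids]
    recs = []
    for fid in table.feature_ids:
        x = sub[fid].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if len(x) < 2:
            recs.append(FilterRecord(fid, "qc_cv", np.nan, "removed",
                                     "insufficient_qc_data"))
            continue
        mean = x.mean()
        if mean <= 0:
            recs.append(FilterRecord(fid, "qc_cv", np.nan, "removed",
                                     "nonpositive_qc_mean"))
            continue
        cv = 100.0 * x.std(ddof=1) / mean
        recs.append(FilterRecord(fid, "qc_cv", cv,
                                 "retained" if cv <= cv_threshold else "removed"))
    return FilterReport.from_records(recs)


def filter_missingness(table: FeatureTable, max_missing: float = 0.20) -> FilterReport:
    """Retain features with missing fraction <= max_missing.

    The fraction is computed over study + qc samples (blanks are not part
    of the quantified dataset). Strictly-more-than is removed: exactly 20%
    missing is retained.
    """
    ids = table.samples.index[table.samples["role"].isin(["study", "qc"])]
    sub = table.intensities.loc[ids]
    frac = sub.isna().mean(axis=0)
    recs = [
        FilterRecord(fid, "missingness", float(frac[fid]),
                     "retained" if frac[fid] <= max_missing else "removed")
        for fid in table.feature_ids
    ]
    return FilterReport.from_records(recs)


def apply_filters(
    table: FeatureTable,
    r2_threshold: float = 0.5,
    cv_threshold: float = 30.0,
    max_missing: float = 0.20,
) -> tuple[FeatureTable, FilterReport]:
    """Zero conversion then the dilution -> qc_cv -> missingness chain.

    Each stage's input is the previous stage's retained set; the returned
    report concatenates all stages (plus a zero_conversion bookkeeping
    stage) and the returned table holds the final retained features.
    """
    table = zeros_to_missing(table)
    n_zero = int((table.intensities.isna()).sum().sum())
    report = FilterReport.from_records(
        [FilterRecord(fid, "zero_conversion", n_zero, "retained")
         for fid in table.feature_ids]
    )

    rep = filter_dilution_response(table, r2_threshold)
    report = report.extend(rep)
    table = table.subset_features(rep.retained_ids("dilution"))

    rep = filter_qc_cv(table, cv_threshold)
    report = report.extend(rep)
    table = table.subset_features(rep.retained_ids("qc_cv"))

    rep = filter_missingness(table, max_missing)
    report = report.extend(rep)
    table = table.subset_features(rep.retained_ids("missingness"))
    return table, report
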