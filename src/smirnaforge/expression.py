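"""Microarray spot QC and normalization, stem-loop qRT-PCR relative
quantification, and miRNA-target expression correlation.

Spot filters follow standard single-channel miRNA array practice: background
subtraction, removal of spots below three background standard deviations or
with replicate CV > 0.5, a low-abundance band below signal 100 (kept but
excluded from variance analysis) and a non-expressed band below signal 30.
LOWESS normalization fits each channel's log-ratio against the per-probe
mean log-signal (MA-style against a mean pseudo-array).

qRT-PCR math: abundance relative to an internal control as 2^dCt with
dCt = Ct_control - Ct_gene, and fold change between samples as 2^-ddCt with
dCt = Ct_gene - Ct_control; both conventions make higher abundance map to a
larger value, and the reference sample maps exactly to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess


@dataclass
class SpotMeasurement:
    probe_id: str
    replicate_signals: list[float]
    background_mean: float
    background_sd: float

    def __post_init__(self):
        if not self.replicate_signals:
            raise ValueError("at least one replicate signal required")
        if not all(np.isfinite(self.replicate_signals)):
            raise ValueError("non-finite replicate signal")


@dataclass
class ExpressionCall:
    probe_id: str
    normalized_signal: float
    cv: float
    status: str  # expressed | low_abundance | non_expressed | removed_qc


def microarray_qc(
    spots: list[SpotMeasurement],
    bsd_fold: float = 3.0,
    max_cv: float = 0.5,
    low_abundance_signal: float = 100.0,
    non_expressed_signal: float = 30.0,
) -> list[ExpressionCall]:
    """Background-subtract and QC spot signals into mutually exclusive
    statuses.  CV is computed on background-subtracted replicate signals
    (sample standard deviation / mean)."""
    calls = []
    for spot in spots:
        reps = np.asarray(spot.replicate_signals, dtype=float) - spot.background_mean
        signal = float(reps.mean())
        if len(reps) > 1 and signal != 0:
            cv = float(reps.std(ddof=1) / abs(signal))
        else:
            cv = 0.0
        if signal < bsd_fold * spot.background_sd or cv > max_cv:
            status = "removed_qc"
        elif signal < non_expressed_signal:
            status = "non_expressed"
        elif signal < low_abundance_signal:
            status = "low_abundance"
        else:
            status = "expressed"
        calls.append(ExpressionCall(spot.probe_id, signal, cv, status))
    return calls


def lowess_normalize(
    channels: pd.DataFrame,
    span: float = 0.3,
) -> pd.DataFrame:
    """Intensity-dependent (MA-style) normalization of >= 2 channels sharing
    probes (rows = probes, columns = channels, positive signals).

    Each channel's log2 ratio against the per-probe mean log2 signal is
    smoothed by locally weighted regression over intensity and subtracted.
    Identical channels are returned unchanged."""
    if channels.shape[0] < 10:
        raise ValueError("need at least 10 shared probes for a stable fit")
    if channels.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    if (channels <= 0).any().any():
        raise ValueError("signals must be positive for log transformation")
    log = np.log2(channels.astype(float))
    a = log.mean(axis=1)
    out = {}
    for col in channels.columns:
        m = log[col] - a
        fitted = _sm_lowess(m.to_numpy(), a.to_numpy(), frac=span,
                            return_sorted=False)
        out[col] = np.power(2.0, log[col] - fitted)
    return pd.DataFrame(out, index=channels.index)


def _mean_ct(ct_table: pd.DataFrame, sample: str, gene: str) -> float:
    rows = ct_table[(ct_table["sample"] == sample) & (ct_table["gene"] == gene)]
    if rows.empty:
        raise KeyError(f"no Ct rows for gene {gene!r} in sample {sample!r}")
    return float(rows["ct"].mean())


def rel_expression_dct(
    ct_table: pd.DataFrame, gene: str, sample: str, control: str = "U6"
) -> float:
    """Abundance relative to the internal control: 2^(Ct_control - Ct_gene),
    replicate Cts averaged."""
    dct = _mean_ct(ct_table, sample, control) - _mean_ct(ct_table, sample, gene)
    return float(2.0 ** dct)


def fold_change_ddct(
    ct_table: pd.DataFrame,
    gene: str,
    sample: str,
    reference_sample: str,
    control: str = "U6",
) -> float:
    """Fold change relative to the reference sample: 2^-ddCt with
    dCt = Ct_gene - Ct_control.  The reference sample maps exactly to 1."""
    dct_s = _mean_ct(ct_table, sample, gene) - _mean_ct(ct_table, sample, control)
    dct_r = _mean_ct(ct_table, reference_sample, gene) - _mean_ct(ct_table, reference_sample, control)
    return float(2.0 ** (-(dct_s - dct_r)))


@dataclass
class CorrelationResult:
    pearson_r: float
    spearman_rho: float
    direction: str  # "negative" | "positive"


def correlate_pairs(mirna_profile, target_profile) -> CorrelationResult:
    """Pearson and Spearman correlation of a miRNA and a target expression
    profile over matched tissues; raises on degenerate (zero-variance)
    input."""
    x = np.asarray(mirna_profile, dtype=float)
    y = np.asarray(target_profile, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("profiles must be equal length with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in a profile: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(r, rho, "negative" if r < 0 else "positive")


def spots_from_frame(df: pd.DataFrame) -> list[SpotMeasurement]:
    """Build spot measurements from a signal table with columns
    probe_id, rep1..repN, bg_mean, bg_sd."""
    reps = [c for c in df.columns if c.startswith("rep")]
    return [
        SpotMeasurement(
            probe_id=str(row["probe_id"]),
            replicate_signals=[float(row[c]) for c in reps],
            background_mean=float(row["bg_mean"]),
            background_sd=float(row["bg_sd"]),
        )
        for _, row in df.iterrows()
    ]
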