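"""Count normalization and negative-control process QC.

Two normalizations are provided. ``log2_cpm`` maps a raw count r_gi in a
sample with total R_i to

    y_gi = log2( (r_gi + 0.5) / (R_i + 1) * 1e6 )

The 0.5 offset avoids log of zero and the +1 in the denominator keeps the
ratio strictly below one, so y is always finite. ``median_normalize``
rescales each sample so that its median over miRNA-class probes with
nonzero counts equals a common target (the median of the per-sample
medians); control probes never drive the scaling.

``spc_qc`` applies the statistical-process-control rule used for the
assay's negative-control ("ANT") probes: per sample the mean
negative-control value is computed, the deviation from the grand mean
(Δmean) is charted, and a sample passes iff |Δmean| ≤ 2·SD, where SD is the
sample standard deviation (n−1) of the Δmean values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError

__all__ = ["NormalizedMatrix", "QcReport", "log2_cpm", "median_normalize", "spc_qc"]


@dataclass
class NormalizedMatrix:
    """Probe-by-sample float matrix produced by a normalization step."""

    values: pd.DataFrame
    method: str  # "log2cpm" or "median"
    source: CountMatrix

    def __post_init__(self) -> None:
        if self.method not in ("log2cpm", "median"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("normalized values must be finite")
        if not self.values.index.equals(self.source.counts.index):
            raise ValidationError("normalized matrix lost probe alignment")
        if list(self.values.columns) != list(self.source.counts.columns):
            raise ValidationError("normalized matrix lost sample alignment")

    @property
    def probe_class(self) -> pd.Series:
        return self.source.probe_class

    @property
    def meta(self) -> pd.DataFrame:
        return self.source.meta

    def samples_where(self, tissue=None, stage=None) -> list[str]:
        return self.source.samples_where(tissue=tissue, stage=stage)

    def subset_samples(self, sample_ids) -> "NormalizedMatrix":
        keep = [s for s in self.values.columns if s in set(sample_ids)]
        return NormalizedMatrix(
            values=self.values[keep].copy(),
            method=self.method,
            source=self.source.subset_samples(keep),
        )


@dataclass
class QcReport:
    """Per-sample negative-control chart underlying the ±2SD rule."""

    ant_mean: pd.Series      # per-sample mean over negative-control probes
    grand_mean: float
    delta_mean: pd.Series    # ant_mean - grand_mean
    sd: float                # sample SD (n-1) of delta_mean
    passed: pd.Series        # |delta_mean| <= 2*sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ant_mean": self.ant_mean,
            "delta_mean": self.delta_mean,
            "lower_limit": -2.0 * self.sd,
            "upper_limit": 2.0 * self.sd,
            "pass": self.passed,
        })


def log2_cpm(cm: CountMatrix) -> NormalizedMatrix:
    """log2 counts-per-million with 0.5/1.0 offsets; totals R_i sum every
    probe in the matrix (controls included)."""
    counts = cm.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValidationError(
            f"sample {cm.counts.columns[zero[0]]!r} has zero total counts"
        )
    y = np.log2((counts + 0.5) / (totals[None, :] + 1.0) * 1e6)
    values = pd.DataFrame(y, index=cm.counts.index, columns=cm.counts.columns)
    return NormalizedMatrix(values=values, method="log2cpm", source=cm)


def median_normalize(cm: CountMatrix, on_cpm: bool = False) -> NormalizedMatrix:
    """Scale each sample so per-sample medians agree.

    Medians are taken over miRNA-class probes with nonzero counts in the
    sample (controls and zero counts excluded); each sample is multiplied by
    target/median where the target is the median of the per-sample medians.
    With ``on_cpm=True`` counts are first rescaled to counts-per-million.
    """
    mir = cm.probe_class == "miRNA"
    data = cm.counts.to_numpy(dtype=float)
    if on_cpm:
        totals = data.sum(axis=0)
        if np.any(totals <= 0):
            raise ValidationError("zero total counts; cannot form CPM")
        data = data / totals[None, :] * 1e6
    medians = np.empty(data.shape[1])
    for j in range(data.shape[1]):
        col = data[mir.to_numpy(), j]
        col = col[col > 0]
        if col.size == 0:
            raise ValidationError(
                f"sample {cm.counts.columns[j]!r} has zero median over "
                f"nonzero miRNA probes"
            )
        medians[j] = np.median(col)
    target = float(np.median(medians))
    scaled = data * (target / medians)[None, :]
    values = pd.DataFrame(scaled, index=cm.counts.index, columns=cm.counts.columns)
    return NormalizedMatrix(values=values, method="median", source=cm)


def spc_qc(norm: NormalizedMatrix) -> QcReport:
    """Negative-control process-control chart with the ±2SD acceptance rule."""
    neg = norm.probe_class == "negative_control"
    if int(neg.sum()) < 1:
        raise ValidationError("no negative-control probes present")
    if norm.values.shape[1] < 2:
        raise ValidationError("QC needs at least two samples (SD undefined)")
    ant_mean = norm.values.loc[neg.to_numpy()].mean(axis=0)
    grand = float(ant_mean.mean())
    delta = ant_mean - grand
    sd = float(delta.std(ddof=1))
    passed = delta.abs() <= 2.0 * sd
    return QcReport(
        ant_mean=ant_mean, grand_mean=grand, delta_mean=delta, sd=sd, passed=passed
    )
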