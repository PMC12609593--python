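"""Absolute rDNA copy number from droplet digital PCR counts.

A ddPCR well partitions the reaction into ~20,000 droplets; a droplet is
positive when it received at least one template molecule.  Under random
partitioning the per-droplet occupancy is Poisson, so the mean template
load is recovered from the positive fraction p as

    lambda = -ln(1 - p) * dilution        [copies per droplet, sample scale]

and the sample concentration as lambda / droplet_volume.  The rDNA copy
number per genome is the ratio of the target (28S rDNA, HEX channel) to the
single-copy reference (TBP, FAM channel) concentration, multiplied by the
reference-gene copies per genome ``m_ref``:

    CN = (lambda_target / lambda_reference) * m_ref

``m_ref`` defaults to 1 (haploid sperm genome, one TBP copy); use 2 to
report diploid-genome copy numbers.

Confidence intervals come from Wilson score intervals on each positive
fraction, mapped through -ln(1-p) (monotone), and combined on the log-ratio
scale (delta method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_DROPLET_VOLUME_NL = 0.85  # QX200 droplet volume convention


class SaturationError(ValueError):
    """Raised when every droplet is positive: lambda is unbounded."""


@dataclass
class DropletWell:
    """Counts for one well and one assay channel.

    ``dilution`` is the dilution factor applied to the sample before
    droplet generation for this assay (>= 1); reported lambdas and
    concentrations are corrected back to the undiluted sample.
    """

    well_id: str
    assay: str  # "target" or "reference"
    n_droplets: int
    n_positive: int
    dilution: float = 1.0
    saturated: bool = False

    def __post_init__(self):
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be > 0")
        if not 0 <= self.n_positive <= self.n_droplets:
            raise ValueError("n_positive must be in [0, n_droplets]")
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")


@dataclass
class LambdaEstimate:
    lam: float  # mean copies/droplet, dilution-corrected
    concentration: float  # copies/uL, dilution-corrected
    lam_low: float
    lam_high: float

    @property
    def log_se(self) -> float:
        """Approximate SE of ln(lambda) from the Wilson interval width."""
        if self.lam <= 0 or self.lam_low <= 0:
            return math.inf
        z = sps.norm.ppf(0.975)
        return (math.log(self.lam_high) - math.log(self.lam_low)) / (2 * z)


@dataclass
class CopyNumberEstimate:
    """Absolute copy number per genome with its components."""

    sample_id: str
    lambda_target: float
    lambda_reference: float
    concentration_target: float
    concentration_reference: float
    ratio: float
    m_ref: float
    absolute_cn: float
    ci_low: float
    ci_high: float

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "lambda_target": self.lambda_target,
            "lambda_reference": self.lambda_reference,
            "conc_target_per_ul": self.concentration_target,
            "conc_reference_per_ul": self.concentration_reference,
            "ratio": self.ratio,
            "m_ref": self.m_ref,
            "absolute_cn": self.absolute_cn,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass
class DropletClassification:
    """Droplet category counts from two-channel amplitude thresholding."""

    n_droplets: int
    channels: tuple[str, str]
    n_positive: Mapping[str, int]
    n_double_positive: int
    n_double_negative: int

    def well(self, channel: str, assay: str, well_id: str = "well", dilution: float = 1.0) -> DropletWell:
        return DropletWell(
            well_id=well_id,
            assay=assay,
            n_droplets=self.n_droplets,
            n_positive=int(self.n_positive[channel]),
            dilution=dilution,
        )


def classify_droplets(
    amplitudes: Mapping[str, Iterable[float]] | pd.DataFrame,
    thresholds: Mapping[str, float],
) -> DropletClassification:
    """Threshold per-droplet fluorescence amplitudes into the four categories.

    A droplet is positive on a channel iff its amplitude strictly exceeds
    that channel's threshold (thresholds are operator-chosen inputs, as in
    manual gate adjustment).  Category counts always sum to the droplet
    total.
    """
    if isinstance(amplitudes, pd.DataFrame):
        amplitudes = {c: amplitudes[c].to_numpy() for c in amplitudes.columns}
    missing = [ch for ch in thresholds if ch not in amplitudes]
    if missing:
        raise KeyError(f"amplitude data missing channel(s): {missing}")
    channels = tuple(thresholds.keys())
    if len(channels) != 2:
        raise ValueError("exactly two channels are required")
    arrs = {}
    n = None
    for ch in channels:
        a = np.asarray(list(amplitudes[ch]) if not isinstance(amplitudes[ch], np.ndarray) else amplitudes[ch], dtype=float)
        if a.size == 0:
            raise ValueError("empty amplitude list")
        if not np.isfinite(thresholds[ch]):
            raise ValueError("thresholds must be finite")
        if n is not None and a.size != n:
            raise ValueError("channels must have equal droplet counts")
        n = a.size
        arrs[ch] = a > thresholds[ch]
    ch1, ch2 = channels
    pos1, pos2 = arrs[ch1], arrs[ch2]
    return DropletClassification(
        n_droplets=int(n),
        channels=channels,
        n_positive={ch1: int(pos1.sum()), ch2: int(pos2.sum())},
        n_double_positive=int((pos1 & pos2).sum()),
        n_double_negative=int((~pos1 & ~pos2).sum()),
    )


def estimate_lambda(
    n_positive: int,
    n_droplets: int,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    dilution: float = 1.0,
    confidence: float = 0.95,
) -> LambdaEstimate:
    """Poisson occupancy estimate of copies/droplet and copies/uL.

    The CI is a Wilson score interval on the positive fraction pushed
    through the monotone map p -> -ln(1-p) * dilution.
    """
    if n_droplets <= 0:
        raise ValueError("n_droplets must be > 0")
    if not 0 <= n_positive <= n_droplets:
        raise ValueError("n_positive out of range")
    if n_positive == n_droplets:
        raise SaturationError(
            f"{n_positive}/{n_droplets} droplets positive: occupancy unbounded; dilute the sample"
        )
    p = n_positive / n_droplets
    lam = -math.log1p(-p) * dilution
    lo, hi = _wilson_interval(n_positive, n_droplets, confidence)
    lam_low = -math.log1p(-lo) * dilution
    lam_high = -math.log1p(-min(hi, 1 - 1e-15)) * dilution
    vol_ul = droplet_volume_nl * 1e-3
    return LambdaEstimate(lam=lam, concentration=lam / vol_ul, lam_low=lam_low, lam_high=lam_high)


def _wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    z = sps.norm.ppf(0.5 + confidence / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def copy_number(
    target: DropletWell,
    reference: DropletWell,
    m_ref: float = 1.0,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    confidence: float = 0.95,
    sample_id: str = "",
) -> CopyNumberEstimate:
    """Absolute copy number per genome from a target and a reference well.

    ratio = lambda_target / lambda_reference (both dilution-corrected);
    absolute_cn = ratio * m_ref.  The CI combines the two wells' Wilson
    intervals by the delta method on the log ratio; with zero target
    positives the interval falls back to interval arithmetic on the
    endpoints.
    """
    if target.saturated:
        raise SaturationError(f"target well {target.well_id} flagged saturated")
    t = estimate_lambda(target.n_positive, target.n_droplets, droplet_volume_nl, target.dilution, confidence)
    r = estimate_lambda(reference.n_positive, reference.n_droplets, droplet_volume_nl, reference.dilution, confidence)
    if r.lam == 0:
        raise ValueError(f"reference well {reference.well_id} has zero positives: ratio undefined")
    ratio = t.lam / r.lam
    cn = ratio * m_ref
    z = sps.norm.ppf(0.5 + confidence / 2)
    if t.lam > 0 and math.isfinite(t.log_se) and math.isfinite(r.log_se):
        se = math.sqrt(t.log_se**2 + r.log_se**2)
        ci_low = cn * math.exp(-z * se)
        ci_high = cn * math.exp(z * se)
    else:
        ci_low = t.lam_low / r.lam_high * m_ref
        ci_high = t.lam_high / max(r.lam_low, 1e-300) * m_ref
    return CopyNumberEstimate(
        sample_id=sample_id or target.well_id,
        lambda_target=t.lam,
        lambda_reference=r.lam,
        concentration_target=t.concentration,
        concentration_reference=r.concentration,
        ratio=ratio,
        m_ref=m_ref,
        absolute_cn=cn,
        ci_low=ci_low,
        ci_high=ci_high,
    )


# ------------------------------------------------------------------ table I/O


def read_counts_csv(path) -> pd.DataFrame:
    """Read a droplet-counts table (well_id, sample_id, assay, n_droplets,
    n_positive, dilution)."""
    df = pd.read_csv(path)
    required = {"well_id", "sample_id", "assay", "n_droplets", "n_positive", "dilution"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns: {sorted(missing)}")
    return df


def copy_numbers_from_counts(
    counts: pd.DataFrame,
    m_ref: float = 1.0,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> pd.DataFrame:
    """Per-sample absolute CN table from a long-format counts table."""
    rows = []
    for sample_id, grp in counts.groupby("sample_id", sort=True):
        wells = {}
        for _, rec in grp.iterrows():
            wells[rec["assay"]] = DropletWell(
                well_id=str(rec["well_id"]),
                assay=str(rec["assay"]),
                n_droplets=int(rec["n_droplets"]),
                n_positive=int(rec["n_positive"]),
                dilution=float(rec["dilution"]),
            )
        if "target" not in wells or "reference" not in wells:
            raise ValueError(f"sample {sample_id}: need one 'target' and one 'reference' well")
        est = copy_number(wells["target"], wells["reference"], m_ref=m_ref,
                          droplet_volume_nl=droplet_volume_nl, sample_id=str(sample_id))
        rows.append(est.to_row())
    return pd.DataFrame(rows)
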