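"""Join ddPCR copy numbers with methylation profiles into sample records.

The "presumably active" copy number of a sample is its absolute copy
number (from ddPCR) multiplied by the fraction of bisulfite reads in the
hypomethylated bin (promoter methylation <= 10%); more generally every
10-percentage-point methylation bin gets absolute_cn * bin_fraction
copies, so the unrounded bin copy numbers always sum to the absolute CN.

Semen status follows the WHO 5th-edition reference values: a sample is
NSP (normal semen parameters) iff volume, concentration, motility, and
morphology all meet their thresholds; otherwise ASP with subtype labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

#: WHO 5th-edition lower reference limits (total motility variant).
WHO5_THRESHOLDS: dict[str, float] = {
    "volume": 1.5,  # mL
    "concentration": 15.0,  # 10^6 / mL
    "motility": 40.0,  # % motile (total)
    "morphology": 4.0,  # % normal forms
    "cryptozoospermia": 0.1,  # 10^6 / mL, severe-oligozoospermia cutoff
}

#: Alternative preset using progressive motility >= 32% as the motility rule.
WHO5_PROGRESSIVE_THRESHOLDS: dict[str, float] = {**WHO5_THRESHOLDS, "motility": 32.0}

ASP_SUBTYPES = ("oligozoospermia", "asthenozoospermia", "teratozoospermia", "OAT", "cryptozoospermia")


@dataclass
class SemenClassification:
    semen_class: str  # "NSP" | "ASP" | "unknown"
    subtypes: tuple[str, ...] = ()


def classify_semen(
    volume: float,
    concentration: float,
    motility: float,
    morphology: float,
    thresholds: Mapping[str, float] | None = None,
) -> SemenClassification:
    """WHO-5 semen classification with ASP subtype labels.

    NSP requires every parameter to meet its threshold.  Subtypes:
    oligozoospermia (low concentration), asthenozoospermia (low motility),
    teratozoospermia (low morphology), OAT when all three are low, and
    cryptozoospermia when concentration is below the crypto cutoff.
    Missing (NaN/None) parameters give class "unknown".
    """
    thr = dict(WHO5_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    vals = {"volume": volume, "concentration": concentration,
            "motility": motility, "morphology": morphology}
    for name, v in vals.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return SemenClassification("unknown")
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    low_conc = concentration < thr["concentration"]
    low_mot = motility < thr["motility"]
    low_morph = morphology < thr["morphology"]
    low_vol = volume < thr["volume"]
    if not (low_conc or low_mot or low_morph or low_vol):
        return SemenClassification("NSP")
    subtypes = []
    if low_conc:
        subtypes.append("oligozoospermia")
    if low_mot:
        subtypes.append("asthenozoospermia")
    if low_morph:
        subtypes.append("teratozoospermia")
    if low_conc and low_mot and low_morph:
        subtypes.append("OAT")
    if concentration < thr["cryptozoospermia"]:
        subtypes.append("cryptozoospermia")
    return SemenClassification("ASP", tuple(subtypes))


def binned_copy_numbers(
    absolute_cn: float,
    bin_fractions: Sequence[float],
    tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Copy numbers per methylation bin; the first bin is the active CN.

    Returns the *unrounded* values (bin_cns, active_cn); use
    :func:`rdnacn._util.round_half_up` for reported integers.  The
    unrounded bins sum to ``absolute_cn`` exactly (conservation).
    """
    fr = np.asarray(bin_fractions, dtype=float)
    if absolute_cn < 0:
        raise ValueError("absolute_cn must be >= 0")
    if fr.size != 10:
        raise ValueError("expected 10 bin fractions")
    if (fr < -tol).any() or abs(fr.sum() - 1.0) > max(tol, 1e-9):
        raise ValueError(f"bin fractions must be nonnegative and sum to 1 (got sum {fr.sum()!r})")
    bin_cns = absolute_cn * fr
    return bin_cns, float(bin_cns[0])


@dataclass
class SampleRecord:
    """One donor sample with copy numbers, methylation, and clinical data."""

    sample_id: str
    absolute_cn: float
    methylation_pct: float
    bin_cns: tuple[float, ...]
    active_cn: float
    age: float
    bmi: float
    volume_ml: float
    conc_mio_per_ml: float
    motility_pct: float
    morphology_pct: float
    semen_class: str
    asp_subtypes: tuple[str, ...]
    pregnancy: str  # "yes" | "no" | "unknown"


def build_master_table(
    cn_table: pd.DataFrame,
    profile_table: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    thresholds: Mapping[str, float] | None = None,
    round_reported: bool = False,
) -> pd.DataFrame:
    """Join ddPCR, methylation-profile, and clinical tables on sample_id.

    ``cn_table`` needs sample_id + absolute_cn; ``profile_table`` needs
    sample_id, mean_methylation_pct, hypomethylated_fraction and the ten
    ``bin_*`` columns; the sample sheet carries the clinical covariates.
    Samples flagged ``no_data`` (no retained reads) are dropped with their
    ids noted in ``df.attrs["excluded"]``.  With ``round_reported`` the
    copy-number columns are rounded half-up to integers (as in printed
    per-sample tables); statistics should run on unrounded values.
    """
    bins_cols = [c for c in profile_table.columns if c.startswith("bin_")]
    if len(bins_cols) != 10:
        raise ValueError("profile table must carry the 10 bin_* fraction columns")
    excluded = []
    rows = []
    prof = profile_table.set_index("sample_id")
    cn = cn_table.set_index("sample_id")
    for _, srow in sample_sheet.iterrows():
        sid = srow["sample_id"]
        if sid not in cn.index or sid not in prof.index:
            excluded.append((sid, "missing_stage_output"))
            continue
        p = prof.loc[sid]
        if bool(p.get("no_data", False)):
            excluded.append((sid, "no_data"))
            continue
        abs_cn = float(cn.loc[sid, "absolute_cn"])
        fractions = p[bins_cols].to_numpy(dtype=float)
        bin_cns, active = binned_copy_numbers(abs_cn, fractions)
        cls = classify_semen(
            srow.get("volume_ml", np.nan), srow.get("conc_mio_per_ml", np.nan),
            srow.get("motility_pct", np.nan), srow.get("morphology_pct", np.nan),
            thresholds,
        )
        pregnancy = srow.get("pregnancy", "")
        if not isinstance(pregnancy, str) or pregnancy not in ("yes", "no"):
            pregnancy = "unknown"
        if round_reported:
            abs_rep, active_rep = float(round_half_up(abs_cn)), float(round_half_up(active))
            bins_rep = tuple(float(x) for x in round_half_up(bin_cns))
        else:
            abs_rep, active_rep, bins_rep = abs_cn, active, tuple(bin_cns)
        row = {
            "sample_id": sid,
            "absolute_cn": abs_rep,
            "active_cn": active_rep,
            "methylation_pct": float(p["mean_methylation_pct"]),
            "hypomethylated_fraction": float(p["hypomethylated_fraction"]),
            "age": float(srow.get("age", np.nan)),
            "bmi": float(srow.get("bmi", np.nan)),
            "volume_ml": float(srow.get("volume_ml", np.nan)),
            "conc_mio_per_ml": float(srow.get("conc_mio_per_ml", np.nan)),
            "motility_pct": float(srow.get("motility_pct", np.nan)),
            "morphology_pct": float(srow.get("morphology_pct", np.nan)),
            "semen_class": cls.semen_class,
            "asp_subtypes": ";".join(cls.subtypes),
            "pregnancy": pregnancy,
        }
        for i, v in enumerate(bins_rep):
            row[f"cn_bin_{i}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["excluded"] = excluded
    return df
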