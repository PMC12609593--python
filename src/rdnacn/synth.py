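"""Synthetic cohort, droplet, and bisulfite-read generator.

Emulates the inputs of a sperm rDNA copy-number study: 190 donors (94 with
normal semen parameters, NSP; 96 abnormal, ASP), each carrying a true
absolute rDNA copy number, a fraction of promoter-hypomethylated
("presumably active") copies, semen parameters, age, BMI, and an IVF/ICSI
pregnancy outcome.  Downstream stages then see only what a lab would see:
droplet counts per ddPCR well and bisulfite FASTQ reads per sample, while
truth sidecars keep the generating values for oracle tests.

Generative model (per donor)
----------------------------
* absolute CN ~ truncated Normal(mean 236, SD 58) on [100, 420] copies
  per haploid genome.
* active-copy fraction f = f0 - a_age*(age - age_mean) - a_cn*(CN - cn_mean)
  - ASP offset + noise, clipped to [0.02, 0.98].  The age slope is stated
  in percentage points of promoter methylation per year and converted via
  the spread between the two methylation modes; the CN coupling reflects
  dosage compensation (more copies => larger silenced fraction) and is
  what lets the cohort reach a strong negative age/active-CN rank
  correlation while active CN keeps a realistic spread.
* each rDNA copy is either active (per-CpG methylation probability drawn
  around 2%) or inactive (around 60%); a read samples one copy, so read
  methylation is a two-mode binomial mixture over the 25 CpGs.
* ASP donors have their active fraction reduced so that expected mean
  promoter methylation exceeds NSP by ``asp_methylation_offset``
  percentage points (default 1.8).
* pregnancy ~ Bernoulli(logistic(b0 + b.z)), z = standardized
  (active CN, concentration, motility, morphology, age); default
  coefficients produce roughly balanced outcomes with an absolute-CN gap
  of ~24 copies between outcome groups.

Droplets: a well's positive count is Binomial(n, 1 - exp(-lambda)) with
lambda the mean copies per droplet; the target assay runs in a separate
well at dilution 10 so a ~236-copy target does not saturate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import child_seed, reverse_complement
from .ddpcr import DropletWell
from .integrate import WHO5_THRESHOLDS, classify_semen
from .reference import AmpliconReference, default_reference

METH_MODE_SPREAD_FACTOR = 100.0  # % scale for mode means below


@dataclass(frozen=True)
class PregnancyModel:
    """Logistic model on standardized covariates generating pregnancy."""

    intercept: float = 0.10
    beta_active_cn: float = 0.95
    beta_concentration: float = 0.30
    beta_motility: float = 0.20
    beta_morphology: float = 0.35
    beta_age: float = -0.10
    # standardization constants (cohort-level nominal scales, not refit per draw)
    scales: dict = field(default_factory=lambda: {
        "active_cn": (110.0, 31.0),
        "concentration": (57.0, 47.0),
        "motility": (47.0, 18.0),
        "morphology": (7.0, 3.8),
        "age": (39.0, 7.0),
    })

    def probability(self, active_cn, concentration, motility, morphology, age) -> float:
        z = self.intercept
        for name, val, beta in (
            ("active_cn", active_cn, self.beta_active_cn),
            ("concentration", concentration, self.beta_concentration),
            ("motility", motility, self.beta_motility),
            ("morphology", morphology, self.beta_morphology),
            ("age", age, self.beta_age),
        ):
            mu, sd = self.scales[name]
            z += beta * (val - mu) / sd
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic cohort."""

    n_nsp: int = 94
    n_asp: int = 96
    age_mean: float = 39.0
    age_sd: float = 7.0
    age_bounds: tuple[float, float] = (25.0, 58.0)
    bmi_mean: float = 26.5
    bmi_sd: float = 4.5
    bmi_bounds: tuple[float, float] = (17.0, 52.0)
    abs_cn_mean: float = 236.0
    abs_cn_sd: float = 58.0
    abs_cn_bounds: tuple[float, float] = (100.0, 420.0)
    # methylation model
    active_mode_meth: float = 0.02  # mean per-CpG methylation prob, active copies
    inactive_mode_meth: float = 0.60  # same, inactive copies
    mode_concentration: float = 60.0  # Beta concentration for per-copy draws
    active_fraction_base: float = 0.50  # NSP active fraction at mean age / mean CN
    asp_methylation_offset: float = 1.8  # percentage points of mean methylation
    age_methylation_slope: float = 0.62  # pp of mean methylation per year
    cn_active_coupling: float = 0.00055  # active-fraction decrease per extra copy
    active_fraction_noise_sd: float = 0.055
    pregnancy_model: PregnancyModel = field(default_factory=PregnancyModel)
    n_unknown_pregnancy: int = 1

    def __post_init__(self):
        if self.n_nsp <= 0 or self.n_asp <= 0:
            raise ValueError("group sizes must be > 0")
        lo, hi = self.abs_cn_bounds
        if not (0 < lo < hi):
            raise ValueError("CN bounds must be positive with lower < upper")
        for sd in (self.age_sd, self.bmi_sd, self.abs_cn_sd, self.active_fraction_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.abs_cn_sd == 0 and not (lo <= self.abs_cn_mean <= hi):
            raise ValueError("zero-variance CN spec with bounds excluding the mean")

    @property
    def mode_spread_pp(self) -> float:
        """Percentage-point gap between the inactive and active mode means."""
        return (self.inactive_mode_meth - self.active_mode_meth) * METH_MODE_SPREAD_FACTOR


@dataclass
class DonorTruth:
    """Ground truth behind one synthetic donor sample."""

    sample_id: str
    group: str  # "NSP" | "ASP"
    true_abs_cn: float
    true_active_fraction: float  # fraction of copies in the active (hypomethylated) class
    active_mode_p: float  # per-CpG methylation prob of the active class
    inactive_mode_p: float
    age: float
    bmi: float
    volume_ml: float
    conc_mio_per_ml: float
    motility_pct: float
    morphology_pct: float
    pregnancy: str  # "yes" | "no" | "unknown"

    @property
    def expected_methylation_pct(self) -> float:
        f = self.true_active_fraction
        return 100.0 * (f * self.active_mode_p + (1 - f) * self.inactive_mode_p)

    @property
    def true_active_cn(self) -> float:
        return self.true_abs_cn * self.true_active_fraction


def _truncnorm(rng: np.random.Generator, mean, sd, bounds, size):
    if sd == 0:
        return np.full(size, mean, dtype=float)
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _semen_params_nsp(rng: np.random.Generator, n: int, thr=WHO5_THRESHOLDS) -> pd.DataFrame:
    """Semen parameters that all meet the WHO-5 reference values."""
    conc = np.exp(rng.normal(np.log(75.0), 0.45, n))
    conc = np.clip(conc, thr["concentration"] + 1.0, 250.0)
    mot = np.clip(rng.normal(58, 11, n), thr["motility"], 85)
    morph = np.clip(rng.normal(8.5, 3.0, n), thr["morphology"], 18)
    vol = np.clip(rng.normal(3.3, 1.3, n), thr["volume"], 8.0)
    return pd.DataFrame({"volume_ml": vol, "conc_mio_per_ml": conc,
                         "motility_pct": mot, "morphology_pct": morph})


_ASP_SUBTYPES = ("asthenozoospermia", "OAT", "oligozoospermia", "teratozoospermia", "cryptozoospermia")
_ASP_SUBTYPE_P = (0.51, 0.385, 0.04, 0.04, 0.025)


def _semen_params_asp(rng: np.random.Generator, n: int, thr=WHO5_THRESHOLDS) -> pd.DataFrame:
    """Semen parameters failing WHO-5 in at least one dimension.

    Subtype frequencies mirror a male-factor IVF/ICSI population dominated
    by asthenozoospermia and OAT.
    """
    rows = []
    subtypes = rng.choice(len(_ASP_SUBTYPES), size=n, p=_ASP_SUBTYPE_P)
    for st_idx in subtypes:
        st = _ASP_SUBTYPES[st_idx]
        conc = np.clip(np.exp(rng.normal(np.log(45.0), 0.6)), thr["concentration"], 180.0)
        mot = np.clip(rng.normal(50, 10), thr["motility"], 88)
        morph = np.clip(rng.normal(7, 2.5), thr["morphology"], 15)
        vol = float(np.clip(rng.normal(3.3, 1.5), 0.2, 9.0))
        if st in ("oligozoospermia", "OAT"):
            conc = float(np.clip(np.exp(rng.normal(np.log(6.0), 0.8)), 0.5, thr["concentration"] - 1.0))
        if st == "cryptozoospermia":
            conc = float(rng.uniform(0.01, thr["cryptozoospermia"]))
        if st in ("asthenozoospermia", "OAT"):
            mot = float(np.clip(rng.normal(28, 9), 1.0, thr["motility"] - 1.0))
        if st in ("teratozoospermia", "OAT"):
            morph = float(np.clip(rng.normal(2.0, 1.1), 0.0, thr["morphology"] - 0.5))
        rows.append({"volume_ml": vol, "conc_mio_per_ml": float(conc),
                     "motility_pct": float(mot), "morphology_pct": float(morph)})
    return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> tuple[list[DonorTruth], pd.DataFrame]:
    """Draw the donor cohort; returns (truth list, sample sheet).

    Deterministic given ``seed``.  Every NSP donor passes the WHO-5
    classifier and every ASP donor fails it in at least one parameter.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(child_seed(seed, "cohort"))
    n = spec.n_nsp + spec.n_asp
    groups = ["NSP"] * spec.n_nsp + ["ASP"] * spec.n_asp
    age = _truncnorm(rng, spec.age_mean, spec.age_sd, spec.age_bounds, n)
    bmi = _truncnorm(rng, spec.bmi_mean, spec.bmi_sd, spec.bmi_bounds, n)
    abs_cn = _truncnorm(rng, spec.abs_cn_mean, spec.abs_cn_sd, spec.abs_cn_bounds, n)
    semen = pd.concat(
        [_semen_params_nsp(rng, spec.n_nsp), _semen_params_asp(rng, spec.n_asp)],
        ignore_index=True,
    )
    spread = spec.mode_spread_pp  # pp of methylation per unit active fraction
    f = np.full(n, spec.active_fraction_base)
    f -= spec.age_methylation_slope * (age - spec.age_mean) / spread
    f -= spec.cn_active_coupling * (abs_cn - spec.abs_cn_mean)
    is_asp = np.array([g == "ASP" for g in groups])
    f -= is_asp * spec.asp_methylation_offset / spread
    f += rng.normal(0.0, spec.active_fraction_noise_sd, n)
    f = np.clip(f, 0.02, 0.98)

    donors: list[DonorTruth] = []
    for i in range(n):
        p_preg = spec.pregnancy_model.probability(
            active_cn=abs_cn[i] * f[i],
            concentration=semen.loc[i, "conc_mio_per_ml"],
            motility=semen.loc[i, "motility_pct"],
            morphology=semen.loc[i, "morphology_pct"],
            age=age[i],
        )
        pregnancy = "yes" if rng.random() < p_preg else "no"
        donors.append(DonorTruth(
            sample_id=f"S{i + 1:03d}",
            group=groups[i],
            true_abs_cn=float(abs_cn[i]),
            true_active_fraction=float(f[i]),
            active_mode_p=spec.active_mode_meth,
            inactive_mode_p=spec.inactive_mode_meth,
            age=float(age[i]),
            bmi=float(bmi[i]),
            volume_ml=float(semen.loc[i, "volume_ml"]),
            conc_mio_per_ml=float(semen.loc[i, "conc_mio_per_ml"]),
            motility_pct=float(semen.loc[i, "motility_pct"]),
            morphology_pct=float(semen.loc[i, "morphology_pct"]),
            pregnancy=pregnancy,
        ))
    # blank out pregnancy for a deterministic subset (clinical sheets have gaps)
    for j in range(min(spec.n_unknown_pregnancy, n)):
        idx = int(rng.integers(0, n))
        donors[idx] = replace(donors[idx], pregnancy="unknown")
    sheet = sample_sheet_frame(donors)
    return donors, sheet


def sample_sheet_frame(donors: Sequence[DonorTruth]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": d.sample_id,
        "group": d.group,
        "age": round(d.age, 1),
        "bmi": round(d.bmi, 1),
        "volume_ml": round(d.volume_ml, 1),
        "conc_mio_per_ml": round(d.conc_mio_per_ml, 1),
        "motility_pct": round(d.motility_pct, 1),
        "morphology_pct": round(d.morphology_pct, 1),
        "pregnancy": "" if d.pregnancy == "unknown" else d.pregnancy,
    } for d in donors])


def truth_frame(donors: Sequence[DonorTruth]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": d.sample_id,
        "group": d.group,
        "true_abs_cn": d.true_abs_cn,
        "true_active_fraction": d.true_active_fraction,
        "true_active_cn": d.true_active_cn,
        "expected_methylation_pct": d.expected_methylation_pct,
        "age": d.age,
        "pregnancy": d.pregnancy,
    } for d in donors])


# ------------------------------------------------------------------ droplets


def simulate_droplets(
    true_cn: float,
    n_droplets: int = 20_000,
    ref_lambda: float = 0.0305,
    dilution_target: float = 10.0,
    seed: int = 0,
    well_prefix: str = "well",
) -> tuple[DropletWell, DropletWell]:
    """Simulate one target well (diluted) and one reference well.

    The reference (single-copy gene) loads droplets at ``ref_lambda``
    copies/droplet; the target loads at ``true_cn * ref_lambda /
    dilution_target``.  Positive counts are Binomial draws from the Poisson
    occupancy probabilities.  Saturated parameterizations set the
    ``saturated`` warning flag rather than raising.
    """
    if n_droplets <= 0:
        raise ValueError("n_droplets must be > 0")
    if ref_lambda <= 0:
        raise ValueError("ref_lambda must be > 0")
    if dilution_target < 1:
        raise ValueError("dilution_target must be >= 1")
    if true_cn < 0:
        raise ValueError("true_cn must be >= 0")
    rng = np.random.default_rng(child_seed(seed, "droplets"))
    lam_t = true_cn * ref_lambda / dilution_target
    p_t = -np.expm1(-lam_t)
    p_r = -np.expm1(-ref_lambda)
    sat_t = bool(p_t >= 1 - 1e-12)
    sat_r = bool(p_r >= 1 - 1e-12)
    k_t = int(rng.binomial(n_droplets, min(p_t, 1.0)))
    k_r = int(rng.binomial(n_droplets, min(p_r, 1.0)))
    target = DropletWell(f"{well_prefix}_T", "target", n_droplets, k_t, dilution_target, saturated=sat_t)
    reference = DropletWell(f"{well_prefix}_R", "reference", n_droplets, k_r, 1.0, saturated=sat_r)
    return target, reference


def droplet_counts_frame(donors: Sequence[DonorTruth], seed: int = 0,
                         n_droplets: int = 20_000, ref_lambda: float = 0.0305,
                         dilution_target: float = 10.0) -> pd.DataFrame:
    """Long-format droplet counts table for a whole cohort."""
    rows = []
    for d in donors:
        t, r = simulate_droplets(
            d.true_abs_cn, n_droplets, ref_lambda, dilution_target,
            seed=child_seed(seed, "well", d.sample_id), well_prefix=d.sample_id,
        )
        for w in (t, r):
            rows.append({"well_id": w.well_id, "sample_id": d.sample_id, "assay": w.assay,
                         "n_droplets": w.n_droplets, "n_positive": w.n_positive,
                         "dilution": w.dilution})
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- reads


@dataclass
class SimulatedReads:
    """FASTQ text plus the per-read truth sidecar for one sample."""

    sample_id: str
    fastq_r1: str
    fastq_r2: str | None  # None in single-end mode
    truth: pd.DataFrame  # read_id, copy_class, allele, n_meth, methylation_pct, bin


def simulate_reads(
    donor: DonorTruth,
    ref: AmpliconReference | None = None,
    n_reads: int = 600,
    conversion_failure_rate: float = 0.005,
    seq_error_rate: float = 0.001,
    minor_allele_fraction: float = 0.03,
    seed: int = 0,
    paired: bool = True,
    read_length: int = 150,
    mode_concentration: float = 60.0,
) -> SimulatedReads:
    """Simulate bisulfite amplicon reads for one donor.

    Each read samples one rDNA copy: with probability
    ``donor.true_active_fraction`` an active copy (per-CpG methylation
    probability drawn from a Beta centred on the active mode), otherwise an
    inactive copy.  Unmethylated cytosines read as T except with
    probability ``conversion_failure_rate``; sequencing errors substitute a
    uniformly different base.  Paired mode emits two overlapping mates
    fully covering the amplicon (mate 2 reverse-complemented); single-end
    mode emits the full-length amplicon read.
    """
    if ref is None:
        ref = default_reference()
    for name, rate in (("conversion_failure_rate", conversion_failure_rate),
                       ("seq_error_rate", seq_error_rate),
                       ("minor_allele_fraction", minor_allele_fraction)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if not ref.cpg_positions:
        raise ValueError("reference has no CpG sites")
    rng = np.random.default_rng(child_seed(seed, "reads", donor.sample_id))
    L = ref.length
    base_arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    cpg_pos = np.array(ref.cpg_positions)
    c_mask = base_arr == ord("C")
    non_cpg_c = c_mask.copy()
    non_cpg_c[cpg_pos] = False

    r1_buf, r2_buf = io.StringIO(), io.StringIO()
    truth_rows = []
    for i in range(n_reads):
        is_active = rng.random() < donor.true_active_fraction
        mode = donor.active_mode_p if is_active else donor.inactive_mode_p
        kappa = mode_concentration
        if mode <= 0.0 or mode >= 1.0:
            p_meth = float(mode)  # degenerate mode: no per-copy spread
        else:
            p_meth = rng.beta(mode * kappa, (1 - mode) * kappa)
        meth = rng.random(cpg_pos.size) < p_meth

        seq = base_arr.copy()
        # allele
        minor = rng.random() < minor_allele_fraction
        seq[ref.variant_offset] = ord("A") if minor else ord(ref.major_allele)
        # bisulfite conversion: unmethylated Cs -> T unless conversion fails
        unmeth_c = non_cpg_c.copy()
        unmeth_c[cpg_pos[~meth]] = True
        fail = rng.random(L) < conversion_failure_rate
        convert = unmeth_c & ~fail
        seq[convert] = ord("T")
        # sequencing errors
        if seq_error_rate > 0:
            err = rng.random(L) < seq_error_rate
            if err.any():
                idx = np.where(err)[0]
                for j in idx:
                    choices = [b for b in b"ACGT" if b != seq[j]]
                    seq[j] = choices[rng.integers(0, 3)]
        full = seq.tobytes().decode()
        rid = f"{donor.sample_id}:r{i:06d}"
        qual = "I" * read_length
        if paired:
            mate1 = full[:read_length]
            mate2 = reverse_complement(full[L - read_length:])
            r1_buf.write(f"@{rid}/1\n{mate1}\n+\n{qual}\n")
            r2_buf.write(f"@{rid}/2\n{mate2}\n+\n{qual}\n")
        else:
            r1_buf.write(f"@{rid}\n{full}\n+\n{'I' * L}\n")
        n_meth = int(meth.sum())
        pct = 100.0 * n_meth / cpg_pos.size
        truth_rows.append({
            "read_id": rid,
            "copy_class": "active" if is_active else "inactive",
            "allele": "A" if minor else ref.major_allele,
            "n_meth": n_meth,
            "methylation_pct": pct,
            "bin": 0 if pct <= 10 else min(int(np.ceil(pct / 10)) - 1, 9),
        })
    return SimulatedReads(
        sample_id=donor.sample_id,
        fastq_r1=r1_buf.getvalue(),
        fastq_r2=r2_buf.getvalue() if paired else None,
        truth=pd.DataFrame(truth_rows),
    )
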