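"""Formats, configuration, orchestration, and run reports.

Sample sheets are plain CSV with the header
``sample_id,group,age,bmi,volume_ml,conc_mio_per_ml,motility_pct,
morphology_pct,pregnancy``; droplet data is long-format CSV; bisulfite
reads are FASTQ (plain or gzipped); the amplicon reference is FASTA with
a TSV annotation sidecar.  ``run_all`` wires the stages together
(simulate -> ddpcr -> dbs -> integrate -> stats), writing a manifest with
input hashes, parameters, and the seed at every stage so reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dbs, ddpcr, stats, synth
from ._util import child_seed
from .integrate import build_master_table
from .model import CohortModel
from .reference import AmpliconReference, default_reference

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "age", "bmi", "volume_ml",
                        "conc_mio_per_ml", "motility_pct", "morphology_pct", "pregnancy")
_NUMERIC_SHEET_COLUMNS = ("age", "bmi", "volume_ml", "conc_mio_per_ml",
                          "motility_pct", "morphology_pct")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate the cohort sample sheet.

    Pregnancy values other than yes/no (blank, NA, ...) map to
    ``"unknown"``.  Duplicate sample ids and non-numeric clinical fields
    are errors.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"sample sheet {path} is empty")
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = set(SAMPLE_SHEET_COLUMNS) - {"group"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing required columns: {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample_id(s): {sorted(dup.unique())}")
    for col in _NUMERIC_SHEET_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric values in column {col!r}") from exc
    df["pregnancy"] = df["pregnancy"].map(
        lambda v: v if isinstance(v, str) and v in ("yes", "no") else "unknown")
    return df


def read_fastq(path) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs from a plain or gzipped FASTQ file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(str(path), "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            fh.readline()
            rid = header[1:].rstrip("\n").split("/")[0].split()[0]
            out.append((rid, seq))
    return out


# ---------------------------------------------------------------- RunConfig


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration (echoed into every report)."""

    outdir: str = "rdnacn_out"
    seed: int = 0
    # simulate stage
    simulate: bool = True
    n_nsp: int = 94
    n_asp: int = 96
    n_reads: int = 600
    n_droplets: int = 20_000
    ref_lambda: float = 0.0305
    dilution_target: float = 10.0
    conversion_failure_rate: float = 0.005
    seq_error_rate: float = 0.001
    minor_allele_fraction: float = 0.03
    # real-data inputs (used when simulate is False)
    sample_sheet: str | None = None
    droplet_counts: str | None = None
    fastq_dir: str | None = None
    reference_fasta: str | None = None
    # thresholds
    min_conversion: float = 0.95
    min_cpgs: int = 20
    min_depth: int = 1
    m_ref: float = 1.0
    droplet_volume_nl: float = 0.85
    who5_preset: str = "total"  # "total" | "progressive"
    alpha: float = 0.05
    k_minima: int = 5

    def __post_init__(self):
        if not 0 < self.min_conversion <= 1:
            raise ValueError("min_conversion must be in (0, 1]")
        if not 0 <= self.min_cpgs <= 25:
            raise ValueError("min_cpgs must be in [0, 25]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.m_ref <= 0 or self.droplet_volume_nl <= 0:
            raise ValueError("m_ref and droplet_volume_nl must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.who5_preset not in ("total", "progressive"):
            raise ValueError("who5_preset must be 'total' or 'progressive'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: RunConfig) -> dict:
    """Execute the pipeline end-to-end; returns the run report dict.

    Stages: simulate (optional) -> ddpcr -> dbs -> integrate -> stats.
    Each stage writes its table under ``config.outdir``; a manifest
    records input hashes, the resolved config, and the seed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    from .integrate import WHO5_PROGRESSIVE_THRESHOLDS, WHO5_THRESHOLDS
    thresholds = WHO5_THRESHOLDS if config.who5_preset == "total" else WHO5_PROGRESSIVE_THRESHOLDS

    try:
        if config.simulate:
            ref = default_reference()
            spec = synth.CohortSpec(n_nsp=config.n_nsp, n_asp=config.n_asp)
            donors, sheet = synth.simulate_cohort(spec, seed=config.seed)
            counts = synth.droplet_counts_frame(
                donors, seed=config.seed, n_droplets=config.n_droplets,
                ref_lambda=config.ref_lambda, dilution_target=config.dilution_target)
            sheet.to_csv(out / "sample_sheet.csv", index=False)
            counts.to_csv(out / "droplet_counts.csv", index=False)
            synth.truth_frame(donors).to_csv(out / "truth.csv", index=False)
            ref.to_fasta(out / "amplicon.fasta", out / "amplicon.annot.tsv")
            reads_by_sample = {}
            for donor in donors:
                sim = synth.simulate_reads(
                    donor, ref, n_reads=config.n_reads,
                    conversion_failure_rate=config.conversion_failure_rate,
                    seq_error_rate=config.seq_error_rate,
                    minor_allele_fraction=config.minor_allele_fraction,
                    seed=child_seed(config.seed, "sample_reads", donor.sample_id))
                reads_by_sample[donor.sample_id] = sim
            manifest["stages"]["simulate"] = {"n_donors": len(donors), "seed": config.seed}
            sheet = read_sample_sheet(out / "sample_sheet.csv")
        else:
            if not (config.sample_sheet and config.droplet_counts and config.fastq_dir
                    and config.reference_fasta):
                raise ValueError("non-simulated runs need sample_sheet, droplet_counts, "
                                 "fastq_dir, and reference_fasta paths")
            sheet = read_sample_sheet(config.sample_sheet)
            counts = ddpcr.read_counts_csv(config.droplet_counts)
            ref = AmpliconReference.from_fasta(config.reference_fasta)
            reads_by_sample = None
            for key in ("sample_sheet", "droplet_counts", "reference_fasta"):
                manifest.setdefault("inputs", {})[key] = _sha256(Path(getattr(config, key)))
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs/simulate' failed: {exc}") from exc

    try:
        cn_table = ddpcr.copy_numbers_from_counts(
            counts, m_ref=config.m_ref, droplet_volume_nl=config.droplet_volume_nl)
        _write_tsv(cn_table, out / "copy_numbers.tsv")
        manifest["stages"]["ddpcr"] = {"n_samples": len(cn_table)}
    except Exception as exc:
        raise RuntimeError(f"stage 'ddpcr' failed: {exc}") from exc

    try:
        opts = dbs.CallOptions(min_conversion=config.min_conversion, min_cpgs=config.min_cpgs)
        prof_rows = []
        call_frames = []
        for sid in sheet["sample_id"]:
            if reads_by_sample is not None:
                sim = reads_by_sample[sid]
                pairs = _pairs_from_sim(sim)
            else:
                pairs = _pairs_from_dir(Path(config.fastq_dir), sid)
            calls = dbs.call_reads(pairs, ref, opts)
            prof_rows.append(dbs.profile_sample(calls, sid, min_depth=config.min_depth).to_row())
            frame = dbs.calls_to_frame(calls)
            frame.insert(0, "sample_id", sid)
            call_frames.append(frame)
        profiles = pd.DataFrame(prof_rows)
        _write_tsv(profiles, out / "methylation_profiles.tsv")
        _write_tsv(pd.concat(call_frames, ignore_index=True), out / "read_calls.tsv")
        manifest["stages"]["dbs"] = {"n_samples": len(profiles)}
    except Exception as exc:
        raise RuntimeError(f"stage 'dbs' failed: {exc}") from exc

    try:
        master = build_master_table(cn_table, profiles, sheet, thresholds=thresholds)
        _write_tsv(master, out / "master_table.tsv")
        manifest["stages"]["integrate"] = {
            "n_samples": len(master), "excluded": master.attrs.get("excluded", [])}
    except Exception as exc:
        raise RuntimeError(f"stage 'integrate' failed: {exc}") from exc

    try:
        results = CohortModel(master, alpha=config.alpha, k_minima=config.k_minima).fit()
        report = write_report(results, out / "report.json", manifest)
        _write_tsv(results.group_summaries.reset_index(), out / "group_summaries.tsv")
        _write_tsv(results.comparisons, out / "comparisons.tsv")
        _write_tsv(results.correlations, out / "correlations.tsv")
        with open(out / "summary.txt", "w") as fh:
            fh.write(results.summary() + "\n")
        manifest["stages"]["stats"] = {"complete": True}
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return report


def _pairs_from_sim(sim: synth.SimulatedReads):
    from .model import _fastq_pairs

    return _fastq_pairs(sim.fastq_r1, sim.fastq_r2)


def _pairs_from_dir(fastq_dir: Path, sample_id: str):
    r1 = fastq_dir / f"{sample_id}_R1.fastq"
    r2 = fastq_dir / f"{sample_id}_R2.fastq"
    if not r1.exists():
        r1 = fastq_dir / f"{sample_id}.fastq"
        if not r1.exists():
            raise FileNotFoundError(f"no FASTQ for sample {sample_id} in {fastq_dir}")
        return read_fastq(r1)
    reads1 = read_fastq(r1)
    if r2.exists():
        reads2 = dict(read_fastq(r2))
        return [(rid, s1, reads2[rid]) for rid, s1 in reads1]
    return reads1


def write_report(results, path, manifest: dict | None = None, incomplete: bool = False) -> dict:
    """Serialize fitted cohort results as machine-readable JSON."""
    report: dict = {"incomplete": bool(incomplete)}
    if manifest is not None:
        report["provenance"] = manifest
    gs = {}
    for (group, variable), row in results.group_summaries.iterrows():
        gs.setdefault(group, {})[variable] = {
            "n": int(row["n"]), "mean": float(row["mean"]), "sd": float(row["sd"]),
            "median": float(row["median"]), "range": [float(row["min"]), float(row["max"])],
        }
    report["group_summaries"] = gs
    report["comparisons"] = results.comparisons.to_dict(orient="records")
    report["correlations"] = results.correlations.to_dict(orient="records")
    report["normality"] = results.normality.to_dict(orient="records")
    report["regressions"] = {
        cn: {
            "n": reg.n, "converged": reg.converged, "separation": reg.separation,
            "coefficients": {name: {"coef": float(r["coef"]), "se": float(r["se"]),
                                    "p": float(r["p"])}
                             for name, r in reg.table.iterrows()},
        }
        for cn, reg in results.regressions.items()
    }
    if results.minima is not None:
        m = results.minima
        report["minimum_cn"] = {
            "k": m.k, "overall": list(m.overall_minima), "pregnancy": list(m.pregnancy_minima),
            "floor": m.floor,
            "p": m.comparison.p_value if m.comparison else None,
            "method": m.comparison.method if m.comparison else None,
        }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
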