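"""File formats and run configuration.

Everything on disk is TSV (UTF-8, Unix newlines) except the pedigree, which
uses the whitespace-delimited PLINK ``.fam`` dialect
(``FID IID FATHER MOTHER SEX [PHENO]``, header optional).  Reports are
written as TSV plus JSON with a run-metadata header; writes go through a
``.tmp`` file and an atomic rename so an interrupted run never clobbers a
finished report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecg_traits import EcgRecord, GLOBAL_EXCLUSION_FLAGS, LEADS
from .pedigree import KinshipResult, Pedigree, validate_pedigree

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_cohort",
    "write_cohort",
    "read_dosages",
    "write_dosages",
    "read_catalog",
    "write_catalog",
    "write_kinship",
    "write_report",
    "write_truth",
    "RunConfig",
]

_FAM_HEADERS = {"fid", "#fid", "famid", "iid", "id"}


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8", newline="\n")
    os.replace(tmp, path)


# --------------------------------------------------------------------------- pedigree


def read_pedigree(path: str | Path, missing_code: str = "0") -> Pedigree:
    """Read a PLINK-.fam-dialect pedigree; the header row is auto-detected."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and parts[0].lower() in _FAM_HEADERS:
                continue
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 fields, got {len(parts)}")
            _fid, iid, father, mother, sex = parts[:5]
            rows.append((iid, father, mother, sex))
    return validate_pedigree(rows, missing_code=missing_code)


def write_pedigree(ped: Pedigree, path: str | Path, fid: str = "1") -> None:
    sex_code = {"male": "1", "female": "2"}
    lines = [
        f"{fid} {ind.id} {ind.father or '0'} {ind.mother or '0'} "
        f"{sex_code.get(ind.sex, '0')} 0"
        for ind in ped
    ]
    _atomic_write(Path(path), "\n".join(lines) + "\n")


# --------------------------------------------------------------------------- cohort

_INTERVAL_COLS = ("qrs_ms", "qt_ms", "pr_ms", "heart_rate_bpm", "qrs_axis_deg")
_COVARIATE_COLS = ("sex", "age", "bmi", "height")


def _amp_cols() -> list[str]:
    return [f"{w}_{lead}" for lead in LEADS for w in ("R", "S")]


def write_cohort(records: Iterable[EcgRecord], covariates: pd.DataFrame, path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict = {"id": rec.id}
        for c in _INTERVAL_COLS:
            row[c] = getattr(rec, c)
        for lead in LEADS:
            r, s = rec.amp.get(lead, (np.nan, np.nan))
            row[f"R_{lead}"], row[f"S_{lead}"] = r, s
        for fl in GLOBAL_EXCLUSION_FLAGS:
            row[fl] = int(bool(rec.flags.get(fl, False)))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("id")
    cov = covariates.reindex(df.index)
    out = pd.concat([df, cov[[c for c in ("sex", "age", "bmi", "height") if c in cov.columns]]], axis=1)
    tmp = Path(path).with_suffix(Path(path).suffix + ".tmp")
    out.to_csv(tmp, sep="\t", float_format="%.6g")
    os.replace(tmp, path)


def read_cohort(path: str | Path) -> tuple[list[EcgRecord], pd.DataFrame]:
    """Read a cohort TSV into records plus a covariate frame (indexed by id).

    Heart rate is both an ECG parameter and an adjustment covariate, so it
    is copied into the covariate frame.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str}).set_index("id")
    needed = set(_INTERVAL_COLS) | set(_amp_cols())
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)[:5]} ...")
    records = []
    for iid, row in df.iterrows():
        amp = {}
        for lead in LEADS:
            r, s = row[f"R_{lead}"], row[f"S_{lead}"]
            if pd.notna(r) and pd.notna(s):
                amp[lead] = (float(r), float(s))
        flags = {
            fl: bool(row[fl]) if fl in row and pd.notna(row[fl]) else False
            for fl in GLOBAL_EXCLUSION_FLAGS
        }
        records.append(
            EcgRecord(
                id=str(iid),
                qrs_ms=float(row["qrs_ms"]),
                qt_ms=float(row["qt_ms"]),
                pr_ms=float(row["pr_ms"]),
                heart_rate_bpm=float(row["heart_rate_bpm"]),
                qrs_axis_deg=float(row["qrs_axis_deg"]),
                amp=amp,
                flags=flags,
            )
        )
    cov_cols = [c for c in _COVARIATE_COLS if c in df.columns]
    covariates = df[cov_cols].astype(float)
    covariates["heart_rate"] = df["heart_rate_bpm"].astype(float)
    return records, covariates


# --------------------------------------------------------------------------- dosages / catalog


def write_dosages(dosages: pd.DataFrame, path: str | Path) -> None:
    tmp = Path(path).with_suffix(Path(path).suffix + ".tmp")
    dosages.to_csv(tmp, sep="\t", index_label="id", float_format="%.6g")
    os.replace(tmp, path)


def read_dosages(path: str | Path) -> pd.DataFrame:
    """Read an individuals x SNPs dosage TSV; every dosage must lie in [0, 2].

    Malformed or out-of-range cells are reported with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str}).set_index("id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = vals.isna() & ~raw_na
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}:{line}: malformed numeric cell in column {col!r}")
        out = (vals < 0) | (vals > 2)
        if out.any():
            line = int(np.nonzero(out.to_numpy())[0][0]) + 2
            raise FormatError(
                f"{path}:{line}: dosage {vals[out].iloc[0]} in column {col!r} outside [0, 2]"
            )
        df[col] = vals
    return df


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    tmp = Path(path).with_suffix(Path(path).suffix + ".tmp")
    catalog.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "source_trait": str, "locus": str})
    missing = {"id", "source_trait", "locus", "pvalue"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: catalog missing column(s) {sorted(missing)}")
    return df


def check_ids(pedigree_ids: Sequence[str], other_ids: Sequence[str], what: str) -> None:
    """Every phenotyped/genotyped id must exist in the pedigree."""
    extra = sorted(set(other_ids) - set(pedigree_ids))
    if extra:
        shown = ", ".join(extra[:10])
        raise FormatError(
            f"{len(extra)} id(s) present in {what} but absent from pedigree: {shown}"
        )


# --------------------------------------------------------------------------- kinship / reports


def write_kinship(kin: KinshipResult, path: str | Path, fmt: str = "long") -> None:
    """Write kinship as long-format (id1, id2, phi; upper triangle incl.
    diagonal) or square-matrix TSV."""
    path = Path(path)
    if fmt == "square":
        df = pd.DataFrame(kin.phi, index=kin.ids, columns=kin.ids)
        tmp = path.with_suffix(path.suffix + ".tmp")
        df.to_csv(tmp, sep="\t", index_label="id", float_format="%.8g")
        os.replace(tmp, path)
        return
    if fmt != "long":
        raise ValueError("fmt must be 'long' or 'square'")
    lines = ["id1\tid2\tphi"]
    n = len(kin.ids)
    iu = np.triu_indices(n)
    for a, b in zip(*iu):
        lines.append(f"{kin.ids[a]}\t{kin.ids[b]}\t{kin.phi[a, b]:.8g}")
    _atomic_write(path, "\n".join(lines) + "\n")


def _metadata(seed: int | None, config: dict | None) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str) if config else ""
    return {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
    }


def write_report(
    report,
    out_dir: str | Path,
    seed: int | None = None,
    config: dict | None = None,
    stem: str = "heritability",
) -> tuple[Path, Path]:
    """Write a HeritabilityReport (or any object with ``to_dataframe``) as
    TSV (2-decimal h2 columns) + full-precision JSON with metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = report.to_dataframe()
    meta = _metadata(seed, config)
    tsv_path = out_dir / f"{stem}.tsv"
    rounded = df.copy()
    for col in rounded.columns:
        if col.startswith(("h2_", "delta_h2", "se_")):
            rounded[col] = rounded[col].map(lambda v: f"{v:.2f}")
    header = "".join(f"# {k}: {v}\n" for k, v in meta.items())
    _atomic_write(tsv_path, header + rounded.to_csv(sep="\t", index=False))
    json_path = out_dir / f"{stem}.json"
    payload = {"metadata": meta, "rows": json.loads(df.to_json(orient="records"))}
    _atomic_write(json_path, json.dumps(payload, indent=2) + "\n")
    return tsv_path, json_path


def write_truth(truth: dict, path: str | Path) -> None:
    _atomic_write(Path(path), json.dumps(truth, indent=2, default=str) + "\n")


# --------------------------------------------------------------------------- run configuration


@dataclasses.dataclass
class RunConfig:
    """Run options; every CLI flag overrides the matching key."""

    pedigree: str | None = None
    phenotypes: str | None = None
    dosages: str | None = None
    catalog: str | None = None
    out: str = "out"
    traits: tuple[str, ...] = ("QRS", "QT", "PR", "SL", "CV", "12LS")
    blom_offset: float = 0.375
    mode_12ls: str = "amplitude"
    reml: bool = False
    xatol: float = 1e-8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        cfg = cls(**raw)
        for key in ("pedigree", "phenotypes", "dosages", "catalog"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FormatError(f"configured {key} path does not exist: {p}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
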