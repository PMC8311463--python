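"""Readers and writers for FASTA, peak-list CSV/TSV, MGF and assay CSV.

FASTA headers may carry keyword annotations after the identifier:
``topology=cyclic|linear``, ``cys_state=oxidized|reduced|cam``,
``disulfides=<int>`` (defaults: linear, reduced, 0).  Peak lists are
CSV/TSV with an ``mz[,intensity]`` header and ``#`` comment lines.
MS/MS spectra use MGF (singly charged context).  Assay tables are CSV
with ``concentration,unit,response[,replicate]`` columns.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _mgf

from .errors import FormatError
from .masses import Peptide
from .peaks import PeakList

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peaklist",
    "write_peaklist",
    "read_mgf",
    "write_mgf",
    "read_assay_csv",
]

log = logging.getLogger("cyclopept")

_CYS_ALIASES = {
    "oxidized": "oxidized",
    "reduced": "reduced",
    "cam": "carbamidomethylated",
    "carbamidomethylated": "carbamidomethylated",
}
_CYS_BACK = {"carbamidomethylated": "cam", "oxidized": "oxidized", "reduced": "reduced"}


def _parse_header(description: str, record_no: int) -> tuple[str, dict]:
    parts = description.split()
    name = parts[0] if parts else f"record{record_no}"
    kw: dict = {}
    for tok in parts[1:]:
        if "=" not in tok:
            raise FormatError(
                f"record {record_no} ({name}): malformed header token {tok!r} "
                "(expected key=value)"
            )
        key, val = tok.split("=", 1)
        if key == "topology":
            if val not in ("cyclic", "linear"):
                raise FormatError(f"record {record_no} ({name}): bad topology {val!r}")
            kw["topology"] = val
        elif key == "cys_state":
            if val not in _CYS_ALIASES:
                raise FormatError(f"record {record_no} ({name}): bad cys_state {val!r}")
            kw["cys_state"] = _CYS_ALIASES[val]
        elif key == "disulfides":
            try:
                kw["n_disulfides"] = int(val)
            except ValueError:
                raise FormatError(
                    f"record {record_no} ({name}): disulfides must be an integer"
                ) from None
        else:
            raise FormatError(f"record {record_no} ({name}): unknown keyword {key!r}")
    return name, kw


def read_fasta(path) -> list[tuple[str, Peptide]]:
    """Read annotated FASTA into (name, Peptide) pairs.

    Lowercase sequences are uppercased with a notice; an empty file
    returns an empty list with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        log.warning("no FASTA records in %s", path)
        return []
    out = []
    for i, rec in enumerate(records, start=1):
        name, kw = _parse_header(rec.description, i)
        seq = str(rec.seq)
        if seq != seq.upper():
            log.info("record %d (%s): sequence uppercased", i, name)
            seq = seq.upper()
        try:
            pep = Peptide(seq, **kw)
        except Exception as exc:
            raise FormatError(f"record {i} ({name}): {exc}") from exc
        out.append((name, pep))
    return out


def write_fasta(path, records: list[tuple[str, Peptide]]) -> None:
    with open(path, "w") as fh:
        for name, p in records:
            fh.write(
                f">{name} topology={p.topology} cys_state={_CYS_BACK[p.cys_state]} "
                f"disulfides={p.n_disulfides}\n{p.sequence}\n"
            )


def read_peaklist(path, label: str = "peaks") -> PeakList:
    """Read an ``mz[,intensity]`` CSV/TSV peak list (``#`` comments)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, comment="#", sep=sep)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable peak list: {exc}") from exc
    if "mz" not in df.columns:
        raise FormatError(f"{path}: missing required column 'mz'")
    mz = pd.to_numeric(df["mz"], errors="coerce")
    if mz.isna().any():
        bad = int(mz.isna().idxmax()) + 2
        raise FormatError(f"{path}: non-numeric m/z near line {bad}")
    if "intensity" in df.columns:
        inten = pd.to_numeric(df["intensity"], errors="coerce")
        if inten.isna().any():
            raise FormatError(f"{path}: non-numeric intensity values")
    else:
        inten = pd.Series(np.ones(len(mz)))
    return PeakList(mz=mz.to_numpy(), intensity=inten.to_numpy(), label=label)


def write_peaklist(path, pl: PeakList) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label={pl.label}\n")
        for k, v in pl.metadata.items():
            fh.write(f"# {k}={v}\n")
        fh.write("mz,intensity\n")
        for m, i in zip(pl.mz, pl.intensity):
            fh.write(f"{m:.6f},{i:.6g}\n")


def read_mgf(path) -> list[PeakList]:
    """Read MGF spectra as PeakLists (singly charged context).

    Spectra declaring a charge other than 1+ are rejected.
    """
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader, start=1):
            params = spec.get("params", {})
            charge = params.get("charge")
            if charge:
                z = int(charge[0])
                if z != 1:
                    raise FormatError(
                        f"{path}: spectrum {i} has charge {z}+; only singly "
                        "charged MALDI spectra are supported"
                    )
            pl = PeakList(
                mz=np.asarray(spec["m/z array"], dtype=float),
                intensity=np.asarray(spec["intensity array"], dtype=float),
                label="msms",
                metadata={
                    "title": params.get("title", f"spectrum{i}"),
                    "pepmass": (params.get("pepmass") or (None,))[0],
                },
            )
            spectra.append(pl)
    return spectra


def write_mgf(path, spectra: list[PeakList]) -> None:
    entries = []
    for i, pl in enumerate(spectra, start=1):
        params = {"title": pl.metadata.get("title", f"spectrum{i}"), "charge": "1+"}
        if pl.metadata.get("pepmass") is not None:
            params["pepmass"] = pl.metadata["pepmass"]
        entries.append(
            {
                "m/z array": pl.mz,
                "intensity array": pl.intensity,
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_assay_csv(path) -> pd.DataFrame:
    """Read a dose-response table: concentration, unit, response[, replicate].

    Units must be homogeneous across rows.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable assay table: {exc}") from exc
    required = {"concentration", "unit", "response"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("concentration", "response"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise FormatError(f"{path}: non-numeric values in column {col!r}")
        df[col] = vals
    units = df["unit"].unique()
    if len(units) > 1:
        raise FormatError(
            f"{path}: mixed concentration units {sorted(map(str, units))}"
        )
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return df
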