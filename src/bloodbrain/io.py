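"""Readers and writers for the tabular artifacts of the pipeline.

Canonical on-disk format is tab-separated text. A single provenance line
prefixed with ``#`` is written at the top of every output and skipped on
read. Missing values are encoded as empty cells or ``NA`` and are never
coerced to 0 — a beta of 0 is a meaningful measurement.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tissue labels understood by the sample sheet.
BLOOD = "blood"
BRAIN_REGIONS = ("BA17", "BA20/21", "BA24", "BA35", "BA46")
TISSUES = (BLOOD,) + BRAIN_REGIONS

#: Trait labels for which predictor weight tables exist.
TRAITS = ("smoking", "HDL", "BMI", "alcohol")

PLATFORMS = ("450K", "EPIC", "custom")

_NA_TOKENS = ["", "NA"]
# %.17g round-trips IEEE doubles exactly, comfortably beyond the 10
# significant digits the round-trip contract requires.
_FLOAT_FMT = "%.17g"


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates a structural invariant."""


def _provenance_line(kind: str, **extra: object) -> str:
    from bloodbrain import __version__

    parts = [f"bloodbrain v{__version__}", kind]
    parts += [f"{k}={v}" for k, v in extra.items()]
    return "# " + " | ".join(parts)


def content_hash(path: str | Path) -> str:
    """SHA-256 of a file's bytes, for provenance logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# BetaMatrix


@dataclass
class BetaMatrix:
    """Probes x samples methylation beta values with optional QC side-matrices.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns; entries
        are beta values in [0, 1], NaN marks a missing measurement.
    detection_p
        Optional same-shape matrix of detection p-values in [0, 1].
    beadcount
        Optional same-shape matrix of non-negative bead counts.
    platform
        Array label; metadata only — probe content defines any platform
        intersection downstream.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    beadcount: pd.DataFrame | None = None
    platform: str = "custom"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )
        for name, side in (("detection_p", self.detection_p), ("beadcount", self.beadcount)):
            if side is None:
                continue
            if not side.index.equals(v.index) or not side.columns.equals(v.columns):
                raise ValidationError(f"{name} matrix does not share probe/sample ordering with values")
            s = side.to_numpy(dtype=float)
            if name == "detection_p" and ((s < 0.0) | (s > 1.0)).any():
                raise ValidationError("detection p-value outside [0, 1]")
            if name == "beadcount" and (s < 0.0).any():
                raise ValidationError("negative beadcount")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, probes: Sequence[str] | None = None, samples: Sequence[str] | None = None) -> "BetaMatrix":
        """Return a new matrix restricted to the given probes/samples (order kept as given)."""

        def _cut(df: pd.DataFrame | None) -> pd.DataFrame | None:
            if df is None:
                return None
            out = df
            if probes is not None:
                out = out.loc[list(probes)]
            if samples is not None:
                out = out[list(samples)]
            return out

        return BetaMatrix(
            values=_cut(self.values),
            detection_p=_cut(self.detection_p),
            beadcount=_cut(self.beadcount),
            platform=self.platform,
        )


def read_beta_matrix(
    path: str | Path,
    platform: str = "custom",
    sep: str = "\t",
    detection_p_path: str | Path | None = None,
    beadcount_path: str | Path | None = None,
) -> BetaMatrix:
    """Read a beta matrix (and optional QC side-matrices) from delimited text.

    First column holds probe ids, header row holds sample ids. Empty cells
    and ``NA`` parse as missing. Values outside [0, 1] or duplicate probe
    ids are hard errors.
    """
    values = _read_matrix(path, sep)
    detp = _read_matrix(detection_p_path, sep) if detection_p_path else None
    bead = _read_matrix(beadcount_path, sep) if beadcount_path else None
    m = BetaMatrix(values=values, detection_p=detp, beadcount=bead, platform=platform)
    logger.info("read beta matrix %s: %d probes x %d samples", path, *m.shape)
    return m


def _read_matrix(path: str | Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=sep,
        comment="#",
        index_col=0,
        na_values=_NA_TOKENS,
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    try:
        # str -> float via the exact (correctly rounded) parser so that
        # %.17g output round-trips bitwise
        out = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric value in {path}: {exc}") from exc
    return out


def write_beta_matrix(
    m: BetaMatrix,
    path: str | Path,
    sep: str = "\t",
    detection_p_path: str | Path | None = None,
    beadcount_path: str | Path | None = None,
) -> None:
    """Write a beta matrix (and optional side-matrices) with a provenance header."""
    _write_matrix(m.values, path, sep, kind="beta_matrix", platform=m.platform)
    if detection_p_path is not None and m.detection_p is not None:
        _write_matrix(m.detection_p, detection_p_path, sep, kind="detection_p", platform=m.platform)
    if beadcount_path is not None and m.beadcount is not None:
        _write_matrix(m.beadcount, beadcount_path, sep, kind="beadcount", platform=m.platform)


def _write_matrix(df: pd.DataFrame, path: str | Path, sep: str, kind: str, **extra: object) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(kind, probes=df.shape[0], samples=df.shape[1], **extra) + "\n")
        df.to_csv(fh, sep=sep, float_format=_FLOAT_FMT, na_rep="NA", index_label="probe_id")


# ---------------------------------------------------------------------------
# WeightTable


@dataclass
class WeightTable:
    """Per-trait CpG coefficient list defining a linear methylation predictor."""

    trait: str
    weights: pd.Series  # index: probe ids, values: signed coefficients
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if len(self.weights) < 1:
            raise ValidationError(f"weight table for {self.trait!r} has no entries")
        if self.weights.index.has_duplicates:
            dup = self.weights.index[self.weights.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id in weight table: {dup!r}")
        w = self.weights.to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValidationError(f"non-finite weight in table for {self.trait!r}")
        if not np.isfinite(self.intercept):
            raise ValidationError("non-finite intercept")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.weights.index)


_INTERCEPT_TOKENS = {"(intercept)", "intercept"}


def read_weight_table(path: str | Path, trait: str, sep: str = "\t") -> WeightTable:
    """Read a two-column (probe id, coefficient) file; an optional intercept
    row is recognized by the probe field ``Intercept``/``(Intercept)``.

    A header row is tolerated: if the second field of the first data row is
    not numeric it is treated as a header and skipped.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep if sep != "," else ",")
            if len(parts) != 2:
                raise ValidationError(f"expected 2 columns in {path}, got {len(parts)}: {line!r}")
            rows.append((parts[0].strip(), parts[1].strip()))
    header_tokens = {"probe_id", "probe", "cpg", "id", "coefficient", "coef", "weight", "beta"}
    if rows and (rows[0][0].lower() in header_tokens or rows[0][1].lower() in header_tokens):
        rows = rows[1:]  # header row
    if not rows:
        raise ValidationError(f"empty weight table: {path}")
    intercept = 0.0
    probes: list[str] = []
    coefs: list[float] = []
    for probe, coef in rows:
        try:
            val = float(coef)
        except ValueError as exc:
            raise ValidationError(f"non-numeric coefficient for {probe!r} in {path}: {coef!r}") from exc
        if probe.lower() in _INTERCEPT_TOKENS:
            intercept = val
        else:
            probes.append(probe)
            coefs.append(val)
    table = WeightTable(trait=trait, weights=pd.Series(coefs, index=pd.Index(probes, name="probe_id")), intercept=intercept)
    logger.info("read weight table %s (%s): %d entries, intercept %g", path, trait, len(table), intercept)
    return table


def write_weight_table(w: WeightTable, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line("weight_table", trait=w.trait, entries=len(w)) + "\n")
        fh.write(sep.join(["probe_id", "coefficient"]) + "\n")
        if w.intercept != 0.0:
            fh.write(sep.join(["(Intercept)", _FLOAT_FMT % w.intercept]) + "\n")
        for probe, coef in w.weights.items():
            fh.write(sep.join([str(probe), _FLOAT_FMT % coef]) + "\n")


# ---------------------------------------------------------------------------
# SampleSheet


@dataclass
class SampleSheet:
    """Sample metadata: sample id, individual, tissue and recorded sex."""

    frame: pd.DataFrame  # columns: sample_id, individual_id, tissue, recorded_sex

    REQUIRED = ("sample_id", "individual_id", "tissue", "recorded_sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        f = self.frame
        if f["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        pairs = f[["individual_id", "tissue"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise ValidationError(f"duplicate (individual, tissue) pair: {dup}")
        bad_tissue = set(f["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValidationError(f"unknown tissue labels: {sorted(bad_tissue)}")
        bad_sex = set(f["recorded_sex"]) - {"F", "M", "unknown"}
        if bad_sex:
            raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")

    def samples_for_tissue(self, tissue: str) -> pd.DataFrame:
        return self.frame[self.frame["tissue"] == tissue]

    def individual_of(self, sample_id: str) -> str:
        row = self.frame[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["individual_id"].iloc[0]


def read_sample_sheet(path: str | Path, sep: str = "\t") -> SampleSheet:
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, na_values=_NA_TOKENS, keep_default_na=False)
    return SampleSheet(frame=df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line("sample_sheet", samples=len(sheet.frame)) + "\n")
        sheet.frame.to_csv(fh, sep=sep, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Generic tables (scores, phenotypes, correlation reports)


def write_table(df: pd.DataFrame, path: str | Path, kind: str, sep: str = "\t", **extra: object) -> None:
    """Write any tidy table with a provenance header line."""
    with open(path, "w") as fh:
        fh.write(_provenance_line(kind, rows=len(df), **extra) + "\n")
        df.to_csv(fh, sep=sep, index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", na_values=_NA_TOKENS, keep_default_na=False)


def read_probe_list(path: str | Path) -> set[str]:
    """Plain-text probe list, one id per line (used for blacklists and
    platform restriction sets)."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_probe_list(probes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p}\n")
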