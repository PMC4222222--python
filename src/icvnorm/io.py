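"""Reading, validating and writing per-subject volumetric tables.

The central container is :class:`VolumeTable`: one row per subject holding an
intracranial volume (ICV, in cc), any number of named regional volumes (cc),
and optional ``sex`` / ``age`` / ``group`` annotations.  Tables are read from
delimited text files or assembled subject-by-subject from FreeSurfer
``aseg.stats`` / ``aparc.stats`` outputs; all volumes are held in cc
internally, with cubic millimetres accepted only at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

#: Columns of a VolumeTable frame that are not regional volumes.
META_COLUMNS = ("icv", "sex", "age", "group")

MM3_PER_CC = 1000.0


@dataclass
class VolumeTable:
    """Per-subject ICV and regional volumes.

    Parameters
    ----------
    data : pandas.DataFrame
        Indexed by unique subject id.  Must contain an ``icv`` column
        (strictly positive, finite, cc); every other non-metadata column is a
        region whose values are strictly positive finite volumes in cc or NaN
        for missing.  Optional metadata columns: ``sex`` (``male``/``female``),
        ``age`` (years), ``group`` (opaque label).
    rejections : list of (subject_id, reason)
        Rows or cells dropped during reading/validation, for reporting.
    """

    data: pd.DataFrame
    rejections: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if "icv" not in df.columns:
            raise FormatError("table has no 'icv' column")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate subject ids: {dupes}")
        icv = pd.to_numeric(df["icv"], errors="coerce")
        bad = ~(np.isfinite(icv) & (icv > 0))
        if bad.any():
            raise ValidationError(
                f"nonpositive or non-numeric ICV for subjects {df.index[bad].tolist()}"
            )
        for region in self.region_names:
            v = pd.to_numeric(df[region], errors="coerce")
            invalid = df[region].notna() & ~((v > 0) & np.isfinite(v))
            if invalid.any():
                raise ValidationError(
                    f"region {region!r}: nonpositive volumes for "
                    f"subjects {df.index[invalid].tolist()}"
                )

    # -- accessors -------------------------------------------------------
    @property
    def region_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def pairs(self, region: str) -> tuple[np.ndarray, np.ndarray]:
        """Return aligned (icv, voi) arrays for one region, missing dropped."""
        if region not in self.region_names:
            raise KeyError(f"unknown region {region!r}")
        sub = self.data[["icv", region]].dropna()
        return sub["icv"].to_numpy(float), sub[region].to_numpy(float)

    def subset(self, mask: pd.Series | np.ndarray) -> "VolumeTable":
        return VolumeTable(self.data.loc[mask].copy())

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index_label="subject_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VolumeTable":
        return cls(df.copy())


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_volumes_table(
    path: str | Path,
    *,
    id_col: str | None = None,
    icv_col: str | None = None,
    sep: str | None = None,
    unit: str = "cc",
) -> VolumeTable:
    """Read a delimited per-subject volume table.

    The file needs a subject-id column (``id_col``, default: first column or
    any of ``subject_id``/``subject``/``id``), an ICV column (``icv_col``,
    default: case-insensitive ``icv``), and at least one region column.
    ``unit`` is ``"cc"`` or ``"mm3"``; mm3 values are divided by 1000 on the
    way in.  Rows with nonpositive or non-numeric ICV are rejected and
    logged; nonpositive region values become missing for that region only.
    """
    path = Path(path)
    if unit not in {"cc", "mm3"}:
        raise ValueError(f"unit must be 'cc' or 'mm3', got {unit!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path, sep))
    if df.columns.size < 3:
        raise FormatError(
            f"{path}: need subject-id, ICV and at least one region column"
        )

    if id_col is None:
        candidates = [c for c in df.columns if c.lower() in {"subject_id", "subject", "id"}]
        id_col = candidates[0] if candidates else df.columns[0]
    if id_col not in df.columns:
        raise FormatError(f"{path}: no subject-id column {id_col!r}")

    if icv_col is None:
        candidates = [c for c in df.columns if c.lower() in {"icv", "etiv", "intracranialvol"}]
        if not candidates:
            raise FormatError(f"{path}: no ICV column found")
        icv_col = candidates[0]
    elif icv_col not in df.columns:
        raise FormatError(f"{path}: no ICV column {icv_col!r}")

    df = df.rename(columns={icv_col: "icv"})
    df[id_col] = df[id_col].astype(str)
    if df[id_col].duplicated().any():
        raise ValidationError(
            f"{path}: duplicate subject ids "
            f"{df[id_col][df[id_col].duplicated()].unique().tolist()}"
        )
    df = df.set_index(id_col)
    df.index.name = "subject_id"

    scale = 1.0 / MM3_PER_CC if unit == "mm3" else 1.0
    region_cols = [c for c in df.columns if c not in META_COLUMNS]
    numeric_cols = ["icv", *region_cols]
    for c in numeric_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce") * scale

    rejections: list[tuple[str, str]] = []
    icv_ok = np.isfinite(df["icv"]) & (df["icv"] > 0)
    for sid in df.index[~icv_ok]:
        rejections.append((str(sid), "nonpositive or non-numeric ICV"))
        logger.warning("rejecting subject %s: nonpositive or non-numeric ICV", sid)
    df = df.loc[icv_ok]

    for region in region_cols:
        bad = df[region].notna() & ~(df[region] > 0)
        for sid in df.index[bad]:
            rejections.append((str(sid), f"nonpositive volume in region {region!r}"))
            logger.warning(
                "subject %s: nonpositive %s volume set to missing", sid, region
            )
        df.loc[bad, region] = np.nan

    if len(df) < 3:
        raise InsufficientDataError(
            f"{path}: only {len(df)} usable rows after validation; need >= 3"
        )
    table = VolumeTable(df)
    table.rejections = rejections
    return table


# ---------------------------------------------------------------------------
# FreeSurfer stats files
# ---------------------------------------------------------------------------

_HEMI_PREFIXES = ("left-", "right-", "lh_", "rh_", "lh-", "rh-")


def _canonical_region(name: str, combine_hemispheres: bool) -> str:
    if not combine_hemispheres:
        return name
    low = name.lower()
    for pre in _HEMI_PREFIXES:
        if low.startswith(pre):
            return name[len(pre):]
    return name


def read_freesurfer_stats(
    path: str | Path,
    subject_id: str,
    table: VolumeTable | None = None,
    *,
    measure_col: str | None = None,
    combine_hemispheres: bool = True,
) -> VolumeTable:
    """Append one subject's volumes from a FreeSurfer stats file.

    Handles the ``aseg.stats`` and ``aparc.stats`` text dialects: ``#``
    comment header with a ``# ColHeaders`` line, whitespace-delimited data
    rows, structure names in ``StructName`` and volumes in ``Volume_mm3``
    (aseg) or ``GrayVol`` (aparc).  ICV is taken from the
    ``# Measure EstimatedTotalIntraCranialVol`` header line when present;
    otherwise an ICV already in ``table`` for this subject is kept.  Volumes
    are converted from mm3 to cc.

    With ``combine_hemispheres`` (default), ``Left-``/``Right-`` (and
    ``lh_``/``rh_``) structures are summed into a single region; repeated
    reads for the same subject and region also accumulate, so reading
    ``lh.aparc.stats`` then ``rh.aparc.stats`` yields hemisphere-summed
    cortical volumes.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    icv_cc: float | None = None
    col_headers: list[str] | None = None
    data_rows: list[list[str]] = []
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("ColHeaders"):
                col_headers = body.split()[1:]
            elif body.startswith("Measure") and "EstimatedTotalIntraCranialVol" in body:
                parts = [p.strip() for p in body.split(",")]
                for p in reversed(parts):
                    try:
                        icv_cc = float(p) / MM3_PER_CC
                        break
                    except ValueError:
                        continue
            continue
        data_rows.append(stripped.split())

    if col_headers is None:
        raise FormatError(f"{path}: no '# ColHeaders' line; not a stats file?")
    if "StructName" not in col_headers:
        raise FormatError(f"{path}: no StructName column")
    if measure_col is None:
        for cand in ("Volume_mm3", "GrayVol"):
            if cand in col_headers:
                measure_col = cand
                break
        else:
            raise FormatError(f"{path}: neither Volume_mm3 nor GrayVol column present")
    elif measure_col not in col_headers:
        raise FormatError(f"{path}: no column {measure_col!r}")

    i_name = col_headers.index("StructName")
    i_vol = col_headers.index(measure_col)

    volumes: dict[str, float] = {}
    for row in data_rows:
        if len(row) != len(col_headers):
            raise FormatError(f"{path}: row has {len(row)} fields, expected {len(col_headers)}")
        region = _canonical_region(row[i_name], combine_hemispheres)
        volumes[region] = volumes.get(region, 0.0) + float(row[i_vol]) / MM3_PER_CC

    df = table.data.copy() if table is not None else pd.DataFrame(
        columns=["icv"], index=pd.Index([], name="subject_id")
    )
    subject_id = str(subject_id)
    if subject_id not in df.index:
        df.loc[subject_id] = np.nan
    if icv_cc is not None:
        df.loc[subject_id, "icv"] = icv_cc
    for region, vol in volumes.items():
        if region not in df.columns:
            df[region] = np.nan
        prev = df.loc[subject_id, region]
        df.loc[subject_id, region] = vol + (0.0 if pd.isna(prev) else float(prev))

    out = VolumeTable.__new__(VolumeTable)  # may hold NaN icv mid-assembly
    out.data = df
    out.rejections = list(table.rejections) if table is not None else []
    return out


# ---------------------------------------------------------------------------
# Fit tables
# ---------------------------------------------------------------------------

def write_fit_table(fits: Iterable, path: str | Path) -> pd.DataFrame:
    """Write a CSV of power-law fit results, one region per row.

    Columns ``beta``, ``se``, ``ci_lower``, ``ci_upper`` are rounded to two
    decimals for display, matching the convention of published exponent
    tables; ``*_full`` columns keep full precision so a read-back loses
    nothing.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to write")
    rows = []
    for f in fits:
        flagged = (
            not (f.ci_beta[0] <= 1.0 <= f.ci_beta[1]) if f.converged else None
        )
        rows.append(
            {
                "region": f.region,
                "n": f.n,
                "beta": round(f.beta, 2),
                "se": round(f.se_beta, 2),
                "ci_lower": round(f.ci_beta[0], 2),
                "ci_upper": round(f.ci_beta[1], 2),
                "nonproportional_flag": flagged,
                "alpha": f.alpha,
                "sigma2": f.sigma2,
                "converged": f.converged,
                "beta_full": f.beta,
                "se_full": f.se_beta,
                "ci_lower_full": f.ci_beta[0],
                "ci_upper_full": f.ci_beta[1],
                "sse": f.sse,
                "df": f.df,
                "ci_level": f.ci_level,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(path, index=False)
    return out


def read_fit_table(path: str | Path) -> pd.DataFrame:
    """Read back a fit table written by :func:`write_fit_table`."""
    return pd.read_csv(path)
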