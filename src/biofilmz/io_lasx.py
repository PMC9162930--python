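"""Reading microscope line-profile CSV exports and writing result tables.

Confocal vendor software exports ROI line profiles as delimited text, but
the dialect varies with the instrument PC's locale: the delimiter may be
comma, semicolon or tab, the decimal mark point or comma, and the encoding
anything from UTF-8 to UTF-16 with BOM. Rather than requiring a manual
conversion step before analysis, :func:`read_profiles` sniffs encoding,
delimiter and decimal mark from the file content, so the same numeric
content parses identically in any supported dialect.

Two layouts are supported:

``wide``
    First column is z (µm), every further column one ROI; column order
    left to right assigns roi_id 1..n.
``long``
    Three columns (roi, z, intensity), one row per sample.
"""

from __future__ import annotations

import io
import re
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .profile import ProfileSet, ZProfile

if TYPE_CHECKING:  # pragma: no cover
    from .core import ThicknessResult

__all__ = [
    "read_profiles",
    "write_profiles_wide",
    "write_results",
    "results_frame",
    "ProfileFormatError",
]


class ProfileFormatError(ValueError):
    """Raised when a file cannot be interpreted as a line-profile export."""


_BOMS = (
    (b"\xef\xbb\xbf", "utf-8-sig"),
    (b"\xff\xfe", "utf-16"),
    (b"\xfe\xff", "utf-16"),
)

_LONG_COLUMN_ALIASES = {
    "roi": "roi",
    "roi_id": "roi",
    "region": "roi",
    "z": "z",
    "z_um": "z",
    "depth": "z",
    "position": "z",
    "intensity": "intensity",
    "value": "intensity",
    "mean": "intensity",
    "gray_value": "intensity",
}


def _decode(raw: bytes) -> str:
    """Decode export bytes: BOM first, then UTF-8, then Latin-1."""
    for bom, enc in _BOMS:
        if raw.startswith(bom):
            return raw.decode(enc)
    # UTF-16 without BOM: NUL bytes are a strong signal
    if b"\x00" in raw[:256]:
        for enc in ("utf-16-le", "utf-16-be"):
            try:
                text = raw.decode(enc)
                if "\x00" not in text:
                    return text
            except UnicodeDecodeError:
                pass
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


def _sniff_dialect(text: str) -> tuple[str, str]:
    """Return (delimiter, decimal) from the first data lines."""
    lines = [ln for ln in text.splitlines() if ln.strip()][:20]
    if not lines:
        raise ProfileFormatError("file is empty")
    counts = {d: [ln.count(d) for ln in lines] for d in (";", "\t", ",")}
    delimiter = None
    for d in (";", "\t"):  # unambiguous delimiters take precedence
        c = counts[d]
        if min(c) >= 1:
            delimiter = d
            break
    if delimiter is None:
        c = counts[","]
        if min(c) >= 1:
            delimiter = ","
        else:
            delimiter = ";"  # single-column file; delimiter irrelevant
    decimal = "."
    if delimiter != ",":
        field_re = re.compile(r"(?<![\d,.])\d+,\d+(?![\d,.])")
        if any(field_re.search(ln) for ln in lines[:20]):
            decimal = ","
    return delimiter, decimal


def _is_numeric_token(tok: str, decimal: str) -> bool:
    tok = tok.strip()
    if not tok:
        return False
    if decimal == ",":
        tok = tok.replace(",", ".")
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _detect_layout(columns: Sequence[str]) -> str:
    names = [str(c).strip().lower().replace(" ", "_") for c in columns]
    mapped = {_LONG_COLUMN_ALIASES.get(n) for n in names}
    if len(columns) == 3 and {"roi", "z", "intensity"} <= mapped:
        return "long"
    return "wide"


def read_profiles(path, layout: str = "auto") -> ProfileSet:
    """Read a line-profile CSV export into a :class:`ProfileSet`.

    Parameters
    ----------
    path
        Delimited text file. Encoding (UTF-8, UTF-8-BOM, UTF-16, Latin-1),
        delimiter (comma/semicolon/tab) and decimal mark (point/comma) are
        detected from content.
    layout
        ``"wide"``, ``"long"`` or ``"auto"`` (header inspection).

    Raises
    ------
    ProfileFormatError
        Empty file, no numeric columns, or ragged rows (with row index).
    OSError
        Unreadable path.
    """
    path = Path(path)
    if layout not in ("wide", "long", "auto"):
        raise ValueError(f"unknown layout {layout!r}")
    raw = path.read_bytes()
    text = _decode(raw).replace("\r\n", "\n").replace("\r", "\n")
    delimiter, decimal = _sniff_dialect(text)

    lines = [ln for ln in text.split("\n") if ln.strip()]
    first_fields = lines[0].split(delimiter)
    has_header = not all(_is_numeric_token(f, decimal) for f in first_fields if f.strip())

    df = pd.read_csv(
        io.StringIO(text),
        sep=delimiter,
        decimal=decimal,
        header=0 if has_header else None,
        skip_blank_lines=True,
        dtype=str,
    )
    # trailing delimiters produce entirely empty columns; drop them
    df = df.dropna(axis=1, how="all")
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ProfileFormatError(f"{path}: no data rows found")

    n_data_rows = len(lines) - (1 if has_header else 0)
    if len(df) != n_data_rows:
        raise ProfileFormatError(
            f"{path}: parsed {len(df)} rows but file has {n_data_rows} data lines"
        )
    ragged = df.isna().any(axis=1)
    if ragged.any():
        row = int(np.argmax(ragged.to_numpy()))
        raise ProfileFormatError(f"{path}: ragged row at data row index {row}")

    def to_num(col: pd.Series) -> Optional[np.ndarray]:
        s = col.astype(str).str.strip()
        if decimal == ",":
            s = s.str.replace(",", ".", regex=False)
        vals = pd.to_numeric(s, errors="coerce")
        if vals.isna().any():
            return None
        return vals.to_numpy(dtype=float)

    numeric = {}
    for c in df.columns:
        v = to_num(df[c])
        if v is not None:
            numeric[c] = v
    if not numeric:
        raise ProfileFormatError(f"{path}: no numeric columns after parsing")

    if layout == "auto":
        layout = _detect_layout(list(df.columns)) if has_header else "wide"

    image_id = path.stem
    profiles = []
    if layout == "long":
        names = {
            c: _LONG_COLUMN_ALIASES.get(str(c).strip().lower().replace(" ", "_"))
            for c in df.columns
        }
        try:
            roi_col = next(c for c, m in names.items() if m == "roi")
            z_col = next(c for c, m in names.items() if m == "z")
            int_col = next(c for c, m in names.items() if m == "intensity")
        except StopIteration:
            raise ProfileFormatError(
                f"{path}: long layout needs roi/z/intensity columns, got {list(df.columns)}"
            ) from None
        for col in (roi_col, z_col, int_col):
            if col not in numeric:
                raise ProfileFormatError(f"{path}: column {col!r} is not numeric")
        tidy = pd.DataFrame(
            {"roi": numeric[roi_col], "z": numeric[z_col], "i": numeric[int_col]}
        )
        for roi, grp in tidy.groupby("roi", sort=True):
            profiles.append(
                ZProfile(
                    roi_id=int(roi),
                    image_id=image_id,
                    z=grp["z"].to_numpy(),
                    intensity=grp["i"].to_numpy(),
                )
            )
    else:
        cols = [c for c in df.columns if c in numeric]
        if len(cols) < 2:
            raise ProfileFormatError(
                f"{path}: wide layout needs a z column plus >= 1 intensity column"
            )
        z = numeric[cols[0]]
        for k, c in enumerate(cols[1:], start=1):
            profiles.append(
                ZProfile(roi_id=k, image_id=image_id, z=z, intensity=numeric[c])
            )

    return ProfileSet(profiles=profiles)


def write_profiles_wide(
    pset: ProfileSet,
    path,
    delimiter: str = ",",
    decimal: str = ".",
    encoding: str = "utf-8",
) -> None:
    """Write one image's profiles as a wide-layout CSV (z, ROI1..ROIn).

    Dialect arguments exist mainly to fabricate locale-specific exports in
    tests; the defaults produce a plain UTF-8 comma/point file.
    """
    profiles = list(pset.profiles)
    if not profiles:
        raise ValueError("profile set is empty")
    image_ids = {p.image_id for p in profiles}
    if len(image_ids) != 1:
        raise ValueError("wide layout holds exactly one image per file")
    profiles = sorted(profiles, key=lambda p: p.roi_id)
    z = profiles[0].z

    def fmt(x: float) -> str:
        s = format(float(x), ".6g")
        return s.replace(".", ",") if decimal == "," else s

    lines = [delimiter.join(["z"] + [f"ROI{p.roi_id}" for p in profiles])]
    for i in range(len(z)):
        lines.append(
            delimiter.join([fmt(z[i])] + [fmt(p.intensity[i]) for p in profiles])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding=encoding)


def _flags_str(flags) -> str:
    return "|".join(sorted(flags)) if flags else ""


def results_frame(results: Iterable["ThicknessResult"]) -> pd.DataFrame:
    """Tidy one-row-per-ROI DataFrame of thickness results."""
    rows = []
    for r in results:
        b = r.boundaries
        rows.append(
            {
                "image_id": r.image_id,
                "roi_id": r.roi_id,
                "lower_z": b.lower_z,
                "upper_z": b.upper_z,
                "thickness_um": r.thickness_um,
                "threshold_left": r.threshold_left,
                "threshold_right": r.threshold_right,
                "flags": _flags_str(r.flags),
            }
        )
    return pd.DataFrame(rows)


def write_results(
    results: Sequence["ThicknessResult"],
    path,
    electrode_id: str = "electrode",
) -> dict:
    """Write the per-ROI detail CSV plus per-image and per-electrode summaries.

    All files are UTF-8, comma-delimited, period decimal. Returns a dict of
    the written paths (``detail``, ``images``, ``electrode``).
    """
    from . import stats  # deferred: stats imports core which imports this module's types

    results = list(results)
    if not results:
        raise ValueError("results must be non-empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    detail = results_frame(results)
    detail.to_csv(path, index=False, encoding="utf-8")

    by_image: dict = {}
    for r in results:
        by_image.setdefault(r.image_id, []).append(r)
    image_summaries = [stats.summarize_image(v) for v in by_image.values()]
    img_df = pd.DataFrame([s.as_dict() for s in image_summaries])
    img_path = path.with_name(path.stem + "_images.csv")
    img_df.to_csv(img_path, index=False, encoding="utf-8")

    elec = stats.summarize_electrode(image_summaries, electrode_id=electrode_id)
    elec_df = pd.DataFrame([elec.as_dict()])
    elec_path = path.with_name(path.stem + "_electrode.csv")
    elec_df.to_csv(elec_path, index=False, encoding="utf-8")

    return {"detail": path, "images": img_path, "electrode": elec_path}
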