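"""Readers and writers for the study's plain-text formats.

* cell tables — CSV with header ``slide_id,x_um,y_um,cell_class``;
* tissue maps — PGM rasters (plain P2 or raw P5) with the physical scale
  and slide id carried in a PGM comment line (``# mpp=... slide_id=...``);
* score panels — wide CSV, one row per slide, one column per reader, blank
  cells for readers who did not score a slide;
* cohorts — CSV with slide_id, subtype, Miller-Payne grade and score
  columns.

Round-trip identity: integers survive exactly; reals to within 1e-9.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .synthetic import CELL_CLASSES, CELL_COLUMNS, TissueMap, VALID_LABELS

# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False, columns=list(CELL_COLUMNS), float_format="%.6f")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"slide_id": str, "cell_class": str})
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df.index[~df["cell_class"].isin(CELL_CLASSES)]
    if len(bad):
        raise ParseError(
            f"{path}: row {bad[0] + 2}, column 'cell_class': "
            f"illegal value {df.loc[bad[0], 'cell_class']!r}"
        )
    for col in ("x_um", "y_um"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"{path}: column {col!r} is not numeric")
    return df[list(CELL_COLUMNS)]


# ---------------------------------------------------------------------------
# Tissue maps (PGM)
# ---------------------------------------------------------------------------


def write_tissue_map(tmap: TissueMap, path: str | Path, raw: bool = False) -> None:
    """Write a tissue label raster as PGM (P2 plain text by default, P5 raw
    on request), with mpp and slide_id in a comment line."""
    path = Path(path)
    h, w = tmap.labels.shape
    header = f"{'P5' if raw else 'P2'}\n# mpp={tmap.mpp!r} slide_id={tmap.slide_id}\n{w} {h}\n2\n"
    if raw:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(tmap.labels.astype(np.uint8).tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for row in tmap.labels:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_tissue_map(path: str | Path) -> TissueMap:
    path = Path(path)
    data = path.read_bytes()
    tokens: list[bytes] = []
    meta = {"mpp": None, "slide_id": path.stem}
    i = 0
    # tokenize the header (magic, width, height, maxval), honouring comments
    while len(tokens) < 4 and i < len(data):
        ch = data[i : i + 1]
        if ch == b"#":
            j = data.index(b"\n", i)
            comment = data[i + 1 : j].decode("ascii", "replace").strip()
            m = re.search(r"mpp=([0-9.eE+-]+)", comment)
            if m:
                meta["mpp"] = float(m.group(1))
            m = re.search(r"slide_id=(\S+)", comment)
            if m:
                meta["slide_id"] = m.group(1)
            i = j + 1
        elif ch.isspace():
            i += 1
        else:
            j = i
            while j < len(data) and not data[j : j + 1].isspace() and data[j : j + 1] != b"#":
                j += 1
            tokens.append(data[i:j])
            i = j
    if len(tokens) < 4:
        raise ParseError(f"{path}: truncated PGM header")
    magic = tokens[0].decode("ascii", "replace")
    try:
        w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric PGM header field") from e
    if magic == "P5":
        i += 1  # single whitespace after maxval
        flat = np.frombuffer(data[i : i + w * h], dtype=np.uint8)
    elif magic == "P2":
        try:
            flat = np.array(data[i:].split(), dtype=np.int64)
        except ValueError as e:
            raise ParseError(f"{path}: non-numeric pixel value") from e
    else:
        raise ParseError(f"{path}: not a PGM file (magic {magic!r})")
    if flat.size != w * h:
        raise ParseError(f"{path}: expected {w * h} pixels, found {flat.size}")
    labels = flat.reshape(h, w)
    illegal = np.argwhere(~np.isin(labels, list(VALID_LABELS)))
    if len(illegal):
        r, c = illegal[0]
        raise ParseError(f"{path}: illegal label code {int(labels[r, c])} at row {int(r)}, column {int(c)}")
    if meta["mpp"] is None:
        raise ParseError(f"{path}: missing 'mpp=' metadata comment")
    return TissueMap(labels.astype(np.uint8), mpp=meta["mpp"], slide_id=meta["slide_id"])


# ---------------------------------------------------------------------------
# Score panels
# ---------------------------------------------------------------------------


def write_score_panel(panel: pd.DataFrame, path: str | Path) -> None:
    out = panel.copy()
    out.index.name = "slide_id"
    out.to_csv(path, float_format="%.6f")


def read_score_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"slide_id": str})
    if "slide_id" not in df.columns:
        raise ParseError(f"{path}: missing 'slide_id' column")
    df = df.set_index("slide_id")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"{path}: reader column {col!r} is not numeric")
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            bad = vals[(vals < 0) | (vals > 100)].index[0]
            raise ParseError(f"{path}: slide {bad!r}, reader {col!r}: score outside [0, 100]")
    return df


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

COHORT_REQUIRED = ("slide_id", "subtype", "mp_grade", "responder")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, float_format="%.6f")


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"slide_id": str, "subtype": str})
    missing = set(COHORT_REQUIRED) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df.index[~df["mp_grade"].isin([1, 2, 3, 4, 5])]
    if len(bad):
        raise ParseError(f"{path}: row {bad[0] + 2}: Miller-Payne grade outside 1..5")
    df["responder"] = df["responder"].astype(bool)
    return df
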