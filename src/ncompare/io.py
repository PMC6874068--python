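"""Lane-level RCC files, annotated expression matrices, and the experiment design.

The nCounter Digital Analyzer emits one RCC (Reporter Code Count) text file
per cartridge lane: tag-delimited sections (``<Header>``, ``<Sample_Attributes>``,
``<Lane_Attributes>``, ``<Code_Summary>``) whose ``Code_Summary`` rows are
``CodeClass,Name,Accession,Count``.  This module parses and writes that layout,
reads/writes the annotated log2 matrix dialect used downstream (features in
rows, lanes in columns, headers encoding ``sample_cartridge_scan``), and builds
the four-cartridge two-generation experiment design.

Lane annotation model
---------------------
A lane is identified by ``(cartridge, scan_index, sample_number, replicate)``.
Six biological samples are run in duplicate per 12-lane cartridge and every
cartridge is scanned twice, so the full design has 4 x 12 x 2 = 96 lane-scan
observations.  Matrix column headers encode the lane as
``{token}_{cartridge}_{scan}`` where token 1..6 is replicate 1 and token 7..12
is replicate 2 of samples 1..6.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    DesignError,
    DuplicationError,
    FormatError,
    ParseError,
)

logger = logging.getLogger(__name__)

CARTRIDGES = ("A", "B", "C", "D")
N_SAMPLES = 6
N_REPLICATES = 2
N_SCANS = 2
LANES_PER_CARTRIDGE = N_SAMPLES * N_REPLICATES


class CodeClass(str, Enum):
    """Probe classes of an nCounter code set."""

    ENDOGENOUS = "Endogenous"
    POSITIVE = "Positive"
    NEGATIVE = "Negative"
    HOUSEKEEPING = "Housekeeping"
    LIGATION = "Ligation"
    SPIKEIN = "SpikeIn"


#: CodeClass spellings seen in vendor files, mapped onto the enum.
_CODE_CLASS_ALIASES = {
    "endogenous": CodeClass.ENDOGENOUS,
    "endogenous1": CodeClass.ENDOGENOUS,
    "positive": CodeClass.POSITIVE,
    "negative": CodeClass.NEGATIVE,
    "housekeeping": CodeClass.HOUSEKEEPING,
    "ligation": CodeClass.LIGATION,
    "spikein": CodeClass.SPIKEIN,
}


@dataclass(frozen=True)
class ProbeRecord:
    """One Code_Summary row: a probe and its molecule count in one lane."""

    code_class: CodeClass
    name: str
    accession: str
    count: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ParseError("probe name must be non-empty")
        if self.count < 0:
            raise ParseError(f"probe {self.name!r}: count must be >= 0, got {self.count}")


@dataclass
class LaneRecord:
    """All probe counts of a single cartridge lane at a single scan."""

    lane_id: str
    cartridge: str
    scan_index: int
    sample_number: int
    replicate: int
    fov_count: int
    probes: list[ProbeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cartridge not in CARTRIDGES:
            raise DesignError(f"cartridge must be one of {CARTRIDGES}, got {self.cartridge!r}")
        if self.scan_index not in (1, 2):
            raise DesignError(f"scan_index must be 1 or 2, got {self.scan_index}")
        if not 1 <= self.sample_number <= N_SAMPLES:
            raise DesignError(f"sample_number must be in 1..{N_SAMPLES}, got {self.sample_number}")
        if self.replicate not in (1, 2):
            raise DesignError(f"replicate must be 1 or 2, got {self.replicate}")
        if self.fov_count <= 0:
            raise DesignError(f"fov_count must be positive, got {self.fov_count}")
        names = [p.name for p in self.probes]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DuplicationError(f"duplicate probe names within lane {self.lane_id}: {dupes}")

    @property
    def annotation(self) -> tuple[str, int, int, int]:
        return (self.cartridge, self.scan_index, self.sample_number, self.replicate)


def lane_token(sample_number: int, replicate: int) -> int:
    """Sample token used in matrix headers: 1..6 = replicate 1, 7..12 = replicate 2."""
    return sample_number + N_SAMPLES * (replicate - 1)


def parse_lane_token(token: int) -> tuple[int, int]:
    """Invert :func:`lane_token`: token 1..12 -> (sample_number, replicate)."""
    if not 1 <= token <= 12:
        raise AnnotationError(f"sample token must be in 1..12, got {token}")
    return ((token - 1) % N_SAMPLES) + 1, ((token - 1) // N_SAMPLES) + 1


def lane_column_id(cartridge: str, scan_index: int, sample_number: int, replicate: int,
                   delimiter: str = "_") -> str:
    """Column header for a lane in the annotated-matrix dialect."""
    return delimiter.join(
        (str(lane_token(sample_number, replicate)), cartridge, str(scan_index))
    )


LANE_ANNOTATION_COLUMNS = ("cartridge", "scan_index", "sample_number", "replicate")


@dataclass
class ExpressionMatrix:
    """Features x lanes expression values with probe-class and lane annotations.

    Parameters
    ----------
    values
        DataFrame, features in rows (index = probe names), lanes in columns
        (column ids as produced by :func:`lane_column_id`).
    scale
        ``"linear_counts"`` (all values >= 0) or ``"log2"``.
    feature_annotations
        Per-feature :class:`CodeClass`, indexed like ``values``.
    lane_annotations
        One row per lane (indexed by column id) with columns
        ``cartridge, scan_index, sample_number, replicate``.
    """

    values: pd.DataFrame
    scale: str
    feature_annotations: pd.Series
    lane_annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("linear_counts", "log2"):
            raise FormatError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            raise FormatError("expression matrix contains missing values")
        if self.scale == "linear_counts" and (self.values.to_numpy() < 0).any():
            raise FormatError("linear counts must be non-negative")
        if not self.feature_annotations.index.equals(self.values.index):
            raise FormatError("feature_annotations index does not match matrix rows")
        if list(self.lane_annotations.index) != list(self.values.columns):
            raise FormatError("lane_annotations index does not match matrix columns")
        missing = set(LANE_ANNOTATION_COLUMNS) - set(self.lane_annotations.columns)
        if missing:
            raise FormatError(f"lane_annotations missing columns {sorted(missing)}")
        tuples = [tuple(r) for r in self.lane_annotations[list(LANE_ANNOTATION_COLUMNS)].itertuples(index=False)]
        if len(tuples) != len(set(tuples)):
            raise DuplicationError("duplicate lane annotation tuples")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_lanes(self) -> int:
        return self.values.shape[1]

    def features_of_class(self, code_class: CodeClass) -> pd.Index:
        return self.values.index[self.feature_annotations == code_class]

    def lanes_where(self, cartridge: str | None = None, scan_index: int | None = None) -> list[str]:
        """Column ids matching the given cartridge and/or scan, in matrix order."""
        ann = self.lane_annotations
        mask = pd.Series(True, index=ann.index)
        if cartridge is not None:
            mask &= ann["cartridge"] == cartridge
        if scan_index is not None:
            mask &= ann["scan_index"] == scan_index
        return list(ann.index[mask])

    def lane_lookup(self) -> dict[tuple[str, int, int, int], str]:
        """Map (cartridge, scan_index, sample_number, replicate) -> column id."""
        return {
            (r.cartridge, r.scan_index, r.sample_number, r.replicate): idx
            for idx, r in self.lane_annotations.iterrows()
        }

    def subset_features(self, names: Iterable[str]) -> "ExpressionMatrix":
        names = list(names)
        return ExpressionMatrix(
            values=self.values.loc[names].copy(),
            scale=self.scale,
            feature_annotations=self.feature_annotations.loc[names].copy(),
            lane_annotations=self.lane_annotations.copy(),
        )


def matrix_from_lanes(lanes: Sequence[LaneRecord]) -> ExpressionMatrix:
    """Assemble per-lane RCC records into a linear-count :class:`ExpressionMatrix`.

    All lanes must carry the same probe set; probe order follows the first lane.
    """
    if not lanes:
        raise FormatError("no lanes given")
    first = lanes[0]
    names = [p.name for p in first.probes]
    classes = {p.name: p.code_class for p in first.probes}
    columns: dict[str, list[int]] = {}
    annotations = []
    for lane in lanes:
        lane_names = [p.name for p in lane.probes]
        if lane_names != names:
            if set(lane_names) != set(names):
                raise FormatError(
                    f"lane {lane.lane_id}: probe set differs from first lane"
                )
            by_name = {p.name: p for p in lane.probes}
            counts = [by_name[n].count for n in names]
        else:
            counts = [p.count for p in lane.probes]
        col = lane_column_id(lane.cartridge, lane.scan_index, lane.sample_number, lane.replicate)
        if col in columns:
            raise DuplicationError(f"two lanes share annotation {col}")
        columns[col] = counts
        annotations.append((col, *lane.annotation))
    values = pd.DataFrame(columns, index=pd.Index(names, name="feature"), dtype=float)
    lane_ann = pd.DataFrame(
        [a[1:] for a in annotations],
        index=pd.Index([a[0] for a in annotations], name="lane"),
        columns=list(LANE_ANNOTATION_COLUMNS),
    )
    feat_ann = pd.Series([classes[n] for n in names], index=values.index, name="code_class")
    return ExpressionMatrix(values, "linear_counts", feat_ann, lane_ann)


# ---------------------------------------------------------------------------
# RCC reading and writing
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^<(/?)([A-Za-z_]+)>\s*$")


def _split_sections(text: str, path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.rstrip("\r\n")
        m = _SECTION_RE.match(line.strip())
        if m:
            closing, name = m.group(1) == "/", m.group(2)
            if closing:
                current = None
            else:
                current = name
                sections.setdefault(name, [])
            continue
        if current is not None and line.strip():
            sections[current].append(line)
    if "Code_Summary" not in sections:
        raise FormatError(f"{path}: missing Code_Summary section")
    return sections


def _attrs(lines: list[str]) -> dict[str, str]:
    out = {}
    for line in lines:
        parts = line.split(",", 1)
        if len(parts) == 2:
            out[parts[0].strip()] = parts[1].strip()
    return out


def read_rcc(path: str | Path) -> LaneRecord:
    """Parse one RCC lane file.

    Unknown code classes are mapped to ``Endogenous`` with a logged warning.
    Counts must be integers; a fractional count names the offending row.
    """
    path = Path(path)
    sections = _split_sections(path.read_text(), path)
    lane_attrs = _attrs(sections.get("Lane_Attributes", []))
    sample_attrs = _attrs(sections.get("Sample_Attributes", []))

    cartridge = lane_attrs.get("CartridgeID", "A")
    scan_index = int(lane_attrs.get("ScanIndex", 1))
    fov_count = int(lane_attrs.get("FovCount", 1))
    lane_pos = int(lane_attrs.get("ID", 1))
    if "SampleNumber" in lane_attrs and "Replicate" in lane_attrs:
        sample_number = int(lane_attrs["SampleNumber"])
        replicate = int(lane_attrs["Replicate"])
    else:
        sample_number, replicate = parse_lane_token(lane_pos)
    lane_id = sample_attrs.get("ID", f"{cartridge}-{lane_pos}-scan{scan_index}")

    probes: list[ProbeRecord] = []
    rows = sections["Code_Summary"]
    if rows and rows[0].lower().startswith("codeclass"):
        rows = rows[1:]
    for row in rows:
        parts = [p.strip() for p in row.split(",")]
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed Code_Summary row {row!r}")
        cls_raw, name, accession, count_raw = parts[0], parts[1], parts[2], parts[3]
        cls = _CODE_CLASS_ALIASES.get(cls_raw.lower())
        if cls is None:
            logger.warning("%s: unknown code class %r for probe %r; treating as Endogenous",
                           path, cls_raw, name)
            cls = CodeClass.ENDOGENOUS
        try:
            count = int(count_raw)
        except ValueError as exc:
            raise ParseError(
                f"{path}: non-integer count {count_raw!r} in row {row!r}"
            ) from exc
        probes.append(ProbeRecord(cls, name, accession, count))
    return LaneRecord(
        lane_id=lane_id,
        cartridge=cartridge,
        scan_index=scan_index,
        sample_number=sample_number,
        replicate=replicate,
        fov_count=fov_count,
        probes=probes,
    )


def write_rcc(lane: LaneRecord, path: str | Path) -> Path:
    """Write a :class:`LaneRecord` as an RCC file that :func:`read_rcc` inverts."""
    path = Path(path)
    lines = [
        "<Header>",
        "FileVersion,1.7",
        "SoftwareVersion,ncompare",
        "</Header>",
        "<Sample_Attributes>",
        f"ID,{lane.lane_id}",
        "</Sample_Attributes>",
        "<Lane_Attributes>",
        f"ID,{lane_token(lane.sample_number, lane.replicate)}",
        f"FovCount,{lane.fov_count}",
        f"CartridgeID,{lane.cartridge}",
        f"ScanIndex,{lane.scan_index}",
        f"SampleNumber,{lane.sample_number}",
        f"Replicate,{lane.replicate}",
        "</Lane_Attributes>",
        "<Code_Summary>",
        "CodeClass,Name,Accession,Count",
    ]
    for p in lane.probes:
        lines.append(f"{p.code_class.value},{p.name},{p.accession},{p.count}")
    lines += ["</Code_Summary>", ""]
    path.write_text("\n".join(lines))
    return path


def read_rcc_dir(directory: str | Path) -> list[LaneRecord]:
    """Read every ``*.RCC``/``*.rcc`` file under a directory (sorted by name)."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".rcc")
    if not paths:
        raise FormatError(f"no RCC files found in {directory}")
    return [read_rcc(p) for p in paths]


# ---------------------------------------------------------------------------
# Annotated matrix dialect
# ---------------------------------------------------------------------------

def _sniff_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_annotated_matrix(path: str | Path, delimiter: str = "_") -> ExpressionMatrix:
    """Read a log2 matrix whose headers encode ``sample_cartridge_scan``.

    The file is tab- or comma-delimited; the first column holds feature names.
    Header tokens are split on ``delimiter`` in the order sample token /
    cartridge / scan index.  Feature order is preserved.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    sep = _sniff_sep(first)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "feature"
    ann_rows = []
    for col in df.columns:
        tokens = str(col).split(delimiter)
        if len(tokens) != 3:
            raise AnnotationError(
                f"{path}: header {col!r} does not split into sample{delimiter}cartridge{delimiter}scan"
            )
        try:
            token = int(tokens[0])
            scan = int(tokens[2])
        except ValueError as exc:
            raise AnnotationError(f"{path}: non-integer token in header {col!r}") from exc
        cartridge = tokens[1]
        sample, replicate = parse_lane_token(token)
        ann_rows.append((cartridge, scan, sample, replicate))
    lane_ann = pd.DataFrame(ann_rows, index=pd.Index(df.columns, name="lane"),
                            columns=list(LANE_ANNOTATION_COLUMNS))
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values / ragged rows")
    feat_ann = pd.Series(CodeClass.ENDOGENOUS, index=df.index, name="code_class")
    return ExpressionMatrix(df.astype(float), "log2", feat_ann, lane_ann)


def write_annotated_matrix(matrix: ExpressionMatrix, path: str | Path,
                           delimiter: str = "_", sep: str = "\t") -> Path:
    """Write the matrix in the dialect :func:`read_annotated_matrix` inverts.

    Column headers are rebuilt from the lane annotations as
    ``{token}{delimiter}{cartridge}{delimiter}{scan}``; values are printed at
    full repr precision so the round trip is exact.
    """
    path = Path(path)
    headers = [
        lane_column_id(r.cartridge, r.scan_index, r.sample_number, r.replicate, delimiter)
        for _, r in matrix.lane_annotations.iterrows()
    ]
    out = matrix.values.copy()
    out.columns = headers
    out.to_csv(path, sep=sep, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Experiment design
# ---------------------------------------------------------------------------

#: Instrument generations of the four cartridges: prep, scanner.
DEFAULT_PREP_GENERATION = {"A": "second", "B": "first", "C": "second", "D": "first"}
DEFAULT_SCANNER_GENERATION = {"A": "second", "B": "first", "C": "first", "D": "second"}
#: Fields of view per scan: 600 on the first-generation scanner, 320 on the second.
FOV_BY_SCANNER_GENERATION = {"first": 600, "second": 320}


@dataclass
class DesignSpec:
    """Cartridge-to-instrument map plus the lane layout.

    ``lanes`` lists every lane-scan observation as
    ``(cartridge, scan_index, sample_number, replicate)``.
    """

    prep_generation: dict[str, str]
    scanner_generation: dict[str, str]
    lanes: list[tuple[str, int, int, int]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, mapping in (("prep_generation", self.prep_generation),
                              ("scanner_generation", self.scanner_generation)):
            for cart, gen in mapping.items():
                if gen not in ("first", "second"):
                    raise DesignError(f"{name}[{cart}] must be 'first' or 'second', got {gen!r}")
        cartridges = sorted({lane[0] for lane in self.lanes})
        for cart in cartridges:
            if cart not in self.prep_generation or cart not in self.scanner_generation:
                raise DesignError(f"cartridge {cart} has no instrument-generation assignment")
            for scan in (1, 2):
                cells = sorted(
                    (s, r) for c, sc, s, r in self.lanes if c == cart and sc == scan
                )
                expected = sorted(
                    (s, r) for s in range(1, N_SAMPLES + 1) for r in (1, 2)
                )
                if cells != expected:
                    raise DesignError(
                        f"cartridge {cart} scan {scan}: expected 6 samples x 2 replicates, "
                        f"got {len(cells)} lanes"
                    )
        if len(self.lanes) != len(set(self.lanes)):
            raise DesignError("duplicate lane-scan observations in design")

    @property
    def cartridges(self) -> list[str]:
        return sorted({lane[0] for lane in self.lanes})

    def n_observations(self) -> int:
        return len(self.lanes)

    def fov_count(self, cartridge: str) -> int:
        return FOV_BY_SCANNER_GENERATION[self.scanner_generation[cartridge]]


def build_design(overrides: Mapping | None = None) -> DesignSpec:
    """Return the default four-cartridge design, optionally overridden.

    The default assigns cartridge A to the second-generation PrepStation and
    scanner, B to the first generation of both, C to second-generation prep
    with the first-generation scanner, and D to the reverse of C.  Overrides
    (``prep_generation``, ``scanner_generation``, ``cartridges``, ``lanes``)
    must keep every cartridge balanced at 6 samples x 2 replicates x 2 scans.
    """
    overrides = dict(overrides or {})
    prep = dict(DEFAULT_PREP_GENERATION)
    scanner = dict(DEFAULT_SCANNER_GENERATION)
    prep.update(overrides.get("prep_generation", {}))
    scanner.update(overrides.get("scanner_generation", {}))
    cartridges = overrides.get("cartridges", list(CARTRIDGES))
    if "lanes" in overrides:
        lanes = [tuple(lane) for lane in overrides["lanes"]]
    else:
        lanes = [
            (cart, scan, sample, rep)
            for cart in cartridges
            for scan in (1, 2)
            for sample in range(1, N_SAMPLES + 1)
            for rep in (1, 2)
        ]
    return DesignSpec(prep_generation=prep, scanner_generation=scanner, lanes=lanes)
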