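"""Per-sample spot tables and GenePix-results-style (GPR) import/export.

The on-disk dialect is a tab-delimited table with a single header row and
one row per spot.  Columns (resolved by name, not position):

``Block`` (1-based subarray), ``Row``, ``Column`` (1-based grid position),
``Name`` (gene id or role token), ``ID``, ``F635 Median``/``B635 Median``
(foreground/background, 635 nm = Cy5 = mock-digested control channel),
``F532 Median``/``B532 Median`` (532 nm = Cy3 = Hin6I-digested test channel)
and ``Flags`` (0 = ok, -50 = unusable spot).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

from .layout import ArrayLayout, SpotRole

FLAG_OK = 0
FLAG_DROPOUT = -50

ROLE_TOKENS = {
    SpotRole.POSITIVE: "POS_CTRL",
    SpotRole.HYB: "HYB_CTRL",
    SpotRole.EMPTY: "EMPTY",
}
_TOKEN_ROLES = {v: k for k, v in ROLE_TOKENS.items()}

GPR_COLUMNS = (
    "Block",
    "Row",
    "Column",
    "Name",
    "ID",
    "F635 Median",
    "B635 Median",
    "F532 Median",
    "B532 Median",
    "Flags",
)


class GPRParseError(ValueError):
    """Raised when a spot table does not match the expected dialect."""


@dataclass
class SpotRecord:
    """One spot of one slide: position, role and two-channel intensities."""

    subarray: int
    row: int
    col: int
    role: SpotRole
    gene_id: Optional[str]
    fg_test: float
    bg_test: float
    fg_control: float
    bg_control: float
    flag: int = FLAG_OK

    def __post_init__(self) -> None:
        for v in (self.fg_test, self.bg_test, self.fg_control, self.bg_control):
            if v < 0:
                raise ValueError("spot intensities must be non-negative")

    @property
    def ok(self) -> bool:
        return self.flag == FLAG_OK


@dataclass
class SampleArray:
    """All spot measurements of one patient sample on the fixed layout."""

    sample_id: str
    layout: ArrayLayout
    spots: List[SpotRecord] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.spots) != self.layout.n_spots:
            raise ValueError(
                f"expected {self.layout.n_spots} spots, found {len(self.spots)}"
            )
        seen = set()
        for s in self.spots:
            key = (s.subarray, s.row, s.col)
            if key in seen:
                raise ValueError(f"duplicate spot position {key}")
            seen.add(key)


def _role_name(record: SpotRecord) -> str:
    if record.role is SpotRole.GENE:
        return record.gene_id or ""
    return ROLE_TOKENS[record.role]


def write_gpr(array: SampleArray, path: Path | str) -> None:
    """Write one sample's spot table in the GPR dialect."""
    path = Path(path)
    lines = ["\t".join(GPR_COLUMNS)]
    for s in array.spots:
        name = _role_name(s)
        lines.append(
            "\t".join(
                (
                    str(s.subarray + 1),
                    str(s.row + 1),
                    str(s.col + 1),
                    name,
                    name,
                    repr(float(s.fg_control)),
                    repr(float(s.bg_control)),
                    repr(float(s.fg_test)),
                    repr(float(s.bg_test)),
                    str(s.flag),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_gpr(
    path: Path | str, layout: ArrayLayout, sample_id: Optional[str] = None
) -> SampleArray:
    """Read a GPR-dialect spot table, validating positions against ``layout``."""
    path = Path(path)
    text = path.read_text().splitlines()
    if not text:
        raise GPRParseError(f"{path}: empty file")
    header = text[0].rstrip("\n").split("\t")
    col_idx = {}
    for col in GPR_COLUMNS:
        try:
            col_idx[col] = header.index(col)
        except ValueError:
            raise GPRParseError(f"{path}: missing column {col!r}") from None

    spots: List[SpotRecord] = []
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < len(header):
            raise GPRParseError(f"{path}:{lineno}: expected {len(header)} columns")

        def get(col: str) -> str:
            return fields[col_idx[col]]

        try:
            sub = int(get("Block")) - 1
            row = int(get("Row")) - 1
            col = int(get("Column")) - 1
            fg_c = float(get("F635 Median"))
            bg_c = float(get("B635 Median"))
            fg_t = float(get("F532 Median"))
            bg_t = float(get("B532 Median"))
            flag = int(get("Flags"))
        except ValueError as exc:
            raise GPRParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        if not (
            0 <= sub < layout.n_subarrays
            and 0 <= row < layout.n_rows
            and 0 <= col < layout.n_cols
        ):
            raise GPRParseError(
                f"{path}:{lineno}: position (block {sub + 1}, row {row + 1}, "
                f"col {col + 1}) outside the {layout.n_subarrays}x"
                f"{layout.n_rows}x{layout.n_cols} layout"
            )
        role, gene = layout.spot_role(row * layout.n_cols + col)
        name = get("Name")
        expected = gene if role is SpotRole.GENE else ROLE_TOKENS[role]
        if name != expected:
            raise GPRParseError(
                f"{path}:{lineno}: spot name {name!r} does not match layout "
                f"({expected!r})"
            )
        spots.append(
            SpotRecord(
                subarray=sub,
                row=row,
                col=col,
                role=role,
                gene_id=gene,
                fg_test=fg_t,
                bg_test=bg_t,
                fg_control=fg_c,
                bg_control=bg_c,
                flag=flag,
            )
        )
    if len(spots) != layout.n_spots:
        raise GPRParseError(
            f"{path}: expected {layout.n_spots} spots, found {len(spots)}"
        )
    array = SampleArray(sample_id=sample_id or path.stem, layout=layout, spots=spots)
    array.validate()
    return array
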