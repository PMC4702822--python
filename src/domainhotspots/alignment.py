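"""Multiple sequence alignment container with residue <-> column maps.

A :class:`DomainAlignment` holds the aligned instances of one protein domain
family. Every coordinate is 1-based: within-instance offsets run from 1 to the
instance length, alignment columns from 1 to the number of columns. The gap
character is ``-`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

GAP = "-"


@dataclass
class DomainAlignment:
    """Aligned domain instances plus per-row offset/column maps.

    Parameters
    ----------
    domain_acc
        Domain accession shared by every row.
    rows
        Ordered ``(row_id, aligned_sequence)`` pairs. All aligned sequences
        must have equal length; ``row_id`` is the instance identifier.
    """

    domain_acc: str
    rows: list[tuple[str, str]]
    _col_of: dict[str, tuple[int, ...]] = field(init=False, repr=False)
    _row_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("alignment has no rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValidationError(
                f"aligned rows have unequal lengths: {sorted(lengths)}"
            )
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({r for r in ids if ids.count(r) > 1})
            raise ValidationError(f"duplicate row ids in alignment: {dupes}")
        self._row_index = {rid: i for i, (rid, _) in enumerate(self.rows)}
        self._col_of = {}
        for rid, seq in self.rows:
            cols = tuple(c + 1 for c, ch in enumerate(seq) if ch != GAP)
            self._col_of[rid] = cols

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0][1])

    @property
    def row_ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def ungapped(self, row_id: str) -> str:
        """Row sequence with gaps removed (the instance sequence)."""
        return self.rows[self._row_index[row_id]][1].replace(GAP, "")

    def column_of(self, row_id: str, offset: int) -> int:
        """Alignment column (1-based) of a 1-based within-instance offset."""
        cols = self._col_of[row_id]
        if not 1 <= offset <= len(cols):
            raise ValidationError(
                f"offset {offset} outside [1, {len(cols)}] for row {row_id}"
            )
        return cols[offset - 1]

    def offset_at(self, row_id: str, column: int) -> int | None:
        """Within-instance offset at a column, or None if the row is gapped."""
        seq = self.rows[self._row_index[row_id]][1]
        if not 1 <= column <= self.length:
            raise ValidationError(f"column {column} outside [1, {self.length}]")
        if seq[column - 1] == GAP:
            return None
        return sum(1 for ch in seq[: column] if ch != GAP)

    def nongap_fraction(self, column: int) -> float:
        """Fraction of rows carrying a residue (not a gap) at a column."""
        if not 1 <= column <= self.length:
            raise ValidationError(f"column {column} outside [1, {self.length}]")
        n = sum(1 for _, seq in self.rows if seq[column - 1] != GAP)
        return n / len(self.rows)
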