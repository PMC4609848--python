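"""Saturation-offset schedules for multi-offset CEST acquisitions.

A schedule is the ordered list of saturation frequency offsets (ppm relative
to water) together with the number of acquisitions averaged at each offset,
plus a flag for the unsaturated normalization volume.  Schedules can be built
programmatically or parsed from the compact text form used in acquisition
protocols, e.g. ``"0, ±0.25, ±3.5 (8), ±6"`` where ``±x (k)`` expands to
``+x`` and ``-x`` with ``k`` acquisitions each and the multiplicity defaults
to 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["OffsetSchedule", "parse_schedule", "DEFAULT_SCHEDULE_TEXT"]

#: 31-offset protocol: densely sampled near water for field-shift fitting,
#: 8 averages at the +-3.5 ppm amide offsets.
DEFAULT_SCHEDULE_TEXT = (
    "0, ±0.25, ±0.5, ±0.75, ±1 (2), ±1.5 (2), ±2 (2), ±2.5 (2), ±3 (2), "
    "±3.25 (2), ±3.5 (8), ±3.75 (2), ±4 (2), ±4.5, ±5, ±6"
)

_ENTRY_RE = re.compile(
    r"^(?P<pm>±|\+/-|\+-)?\s*(?P<off>-?\d+(?:\.\d+)?)\s*(?:\(\s*(?P<n>\d+)\s*\))?$"
)


@dataclass(frozen=True)
class OffsetSchedule:
    """Ordered saturation offsets with per-offset acquisition counts.

    Parameters
    ----------
    entries:
        Sequence of ``(offset_ppm, n_acquisitions)`` pairs. Offsets must be
        unique; counts must be >= 1.
    includes_unsaturated:
        Whether an unsaturated reference volume accompanies the stack.
    """

    entries: tuple[tuple[float, int], ...]
    includes_unsaturated: bool = True

    def __post_init__(self) -> None:
        offs = [o for o, _ in self.entries]
        if len(set(offs)) != len(offs):
            raise ValueError("duplicate offsets in schedule")
        if any(n < 1 for _, n in self.entries):
            raise ValueError("n_acquisitions must be >= 1 for every entry")

    @property
    def offsets(self) -> list[float]:
        """Unique offsets in schedule order."""
        return [o for o, _ in self.entries]

    @property
    def n_offsets(self) -> int:
        return len(self.entries)

    @property
    def n_acquisitions(self) -> int:
        """Total number of saturated acquisitions (sum of multiplicities)."""
        return sum(n for _, n in self.entries)

    def counts(self) -> dict[float, int]:
        return dict(self.entries)

    def sorted(self) -> "OffsetSchedule":
        return OffsetSchedule(
            tuple(sorted(self.entries)), self.includes_unsaturated
        )

    def acquisition_offsets(self) -> list[float]:
        """One offset per acquired volume, repeats expanded, schedule order."""
        out: list[float] = []
        for off, n in self.entries:
            out.extend([off] * n)
        return out

    def to_text(self) -> str:
        parts = []
        seen: set[float] = set()
        for off, n in self.entries:
            if off in seen:
                continue
            mult = f" ({n})" if n != 1 else ""
            if off > 0 and (-off, n) in self.entries:
                parts.append(f"±{off:g}{mult}")
                seen.update({off, -off})
            else:
                parts.append(f"{off:g}{mult}")
                seen.add(off)
        return ", ".join(parts)

    @classmethod
    def default(cls) -> "OffsetSchedule":
        return parse_schedule(DEFAULT_SCHEDULE_TEXT)


def parse_schedule(text: str, includes_unsaturated: bool = True) -> OffsetSchedule:
    """Parse the compact ``"0, ±0.25, ±3.5 (8)"`` schedule notation.

    ``±x (k)`` expands to the pair ``+x, -x`` each with ``k`` acquisitions;
    the multiplicity defaults to 1 when the parenthesis is absent.  Duplicate
    offsets (after expansion) are a parse error.
    """
    entries: list[tuple[float, int]] = []
    for raw in text.replace("ppm", "").split(","):
        tok = raw.strip()
        if not tok:
            continue
        m = _ENTRY_RE.match(tok)
        if m is None:
            raise ValueError(f"cannot parse schedule entry {tok!r}")
        off = float(m.group("off"))
        n = int(m.group("n") or 1)
        if m.group("pm"):
            if off < 0:
                raise ValueError(f"negative offset with ± sign: {tok!r}")
            if off == 0:
                entries.append((0.0, n))
            else:
                entries.append((+off, n))
                entries.append((-off, n))
        else:
            entries.append((off, n))
    return OffsetSchedule(tuple(entries), includes_unsaturated)
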