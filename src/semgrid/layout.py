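"""Electrode grid geometry: mapping channels to cells of a 2-D array.

A high-density electrode array places many bipolar channels on a small
grid over one muscle region; the layout gives each channel a (row, col)
cell so per-channel quantities can be rendered as spatial maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml


@dataclass
class ElectrodeLayout:
    """Assignment of channels to cells of a ``rows x cols`` grid.

    ``placements`` lists ``(channel_name, row, col)`` in channel order;
    rows/cols are 0-based. Every channel occupies exactly one cell and
    no two channels share one. Not every cell need be occupied.
    """

    rows: int
    cols: int
    placements: list[tuple[str, int, int]]
    inter_electrode_distance_mm: float | None = None
    _cells: dict[tuple[int, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.rows}x{self.cols}")
        cells: dict[tuple[int, int], int] = {}
        names: set[str] = set()
        for idx, (name, r, c) in enumerate(self.placements):
            if name in names:
                raise ValueError(f"channel {name!r} placed more than once")
            names.add(name)
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise ValueError(
                    f"channel {name!r} placed at ({r}, {c}), outside {self.rows}x{self.cols} grid"
                )
            if (r, c) in cells:
                other = self.placements[cells[(r, c)]][0]
                raise ValueError(
                    f"channels {other!r} and {name!r} both placed at cell ({r}, {c})"
                )
            cells[(r, c)] = idx
        self._cells = cells

    @property
    def n_channels(self) -> int:
        return len(self.placements)

    @property
    def channel_names(self) -> list[str]:
        return [p[0] for p in self.placements]

    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (row, col) per channel."""
        return np.array([[r, c] for _, r, c in self.placements], dtype=int)

    @classmethod
    def grid(cls, rows: int, cols: int, inter_electrode_distance_mm: float | None = None) -> "ElectrodeLayout":
        """Dense row-major layout: channel i+1 at cell (i // cols, i % cols)."""
        placements = [
            (f"ch{r * cols + c + 1:02d}", r, c) for r in range(rows) for c in range(cols)
        ]
        return cls(rows, cols, placements, inter_electrode_distance_mm)

    # -- serialization (YAML) --------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "rows": self.rows,
            "cols": self.cols,
            "placements": [
                {"channel": n, "row": r, "col": c} for n, r, c in self.placements
            ],
        }
        if self.inter_electrode_distance_mm is not None:
            d["inter_electrode_distance_mm"] = self.inter_electrode_distance_mm
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeLayout":
        placements = [
            (str(p["channel"]), int(p["row"]), int(p["col"])) for p in d["placements"]
        ]
        return cls(
            rows=int(d["rows"]),
            cols=int(d["cols"]),
            placements=placements,
            inter_electrode_distance_mm=d.get("inter_electrode_distance_mm"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ElectrodeLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def read_layout(path) -> ElectrodeLayout:
    """Read an electrode layout description from a YAML file."""
    return ElectrodeLayout.load(path)
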