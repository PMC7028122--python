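"""Headless engine for the grid visual-search test.

A reference object sits at the centre of a 9 x 7 grid filling a
26 cm x 17.3 cm tablet screen viewed from 50 cm; the matching target
appears once at each of the 62 non-centre cells over a run, in an order
randomised per run.  The outcome measure is the response time (RT) at each
location and their overall median.  Peripheral targets take longer to find,
so location eccentricity (degrees of visual angle from screen centre) is
the relevant spatial coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

#: Default refined subset of 22 target locations, (col, row) 1-based with the
#: centre at (5, 4): 4 inner-ring, 8 mid-field and 10 outer cells, symmetric
#: under 180-degree rotation about the centre and spanning all eccentricity
#: bands.  The published refined protocol used a 22-location subset whose
#: exact membership is not enumerated; this layout is this package's
#: documented, non-canonical stand-in and is fully config-overridable.
#: Ordered so that its prefixes form the spatially-distributed refinement
#: ladder: the first 4 are the screen corners, the first 12 add the edge
#: midpoints and the inner ring.
REFINED_22: tuple[tuple[int, int], ...] = (
    (1, 1), (9, 1), (1, 7), (9, 7),
    (1, 4), (9, 4), (5, 1), (5, 7), (4, 4), (6, 4), (5, 3), (5, 5),
    (3, 3), (7, 3), (3, 5), (7, 5), (5, 2), (5, 6), (2, 4), (8, 4),
    (3, 1), (7, 7),
)

#: Nested refinement ladder (subset sizes 4, 12, 22, 62) used for the
#: sparse-locations precision analysis; each rung contains the previous one.
REFINEMENT_LADDER_SIZES: tuple[int, ...] = (4, 12, 22, 62)


@dataclass(frozen=True)
class SearchGrid:
    """Geometry of the 7-row x 9-column search grid.

    Cells are indexed 1-based, row-major from the top-left; the centre cell
    (col 5, row 4) holds the Reference image and is never a target.
    Eccentricity of a cell is atan(planar distance from screen centre /
    viewing distance), in degrees.
    """

    n_cols: int = 9
    n_rows: int = 7
    screen_w_cm: float = 26.0
    screen_h_cm: float = 17.3
    viewing_distance_cm: float = 50.0
    centers_cm: np.ndarray = field(init=False, repr=False)
    ecc_deg: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if min(self.n_cols, self.n_rows) < 1 or self.n_cols % 2 == 0 or self.n_rows % 2 == 0:
            raise ValueError("grid needs odd, positive row and column counts (centre cell)")
        if min(self.screen_w_cm, self.screen_h_cm, self.viewing_distance_cm) <= 0:
            raise ValueError("screen dimensions and viewing distance must be positive")
        cw = self.screen_w_cm / self.n_cols
        ch = self.screen_h_cm / self.n_rows
        cols = np.arange(1, self.n_cols + 1)
        rows = np.arange(1, self.n_rows + 1)
        # screen-centred coordinates: x right, y down, centre cell at (0, 0)
        x = (cols - (self.n_cols + 1) / 2) * cw
        y = (rows - (self.n_rows + 1) / 2) * ch
        xx, yy = np.meshgrid(x, y)
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        ecc = np.degrees(np.arctan(np.hypot(centers[:, 0], centers[:, 1])
                                   / self.viewing_distance_cm))
        object.__setattr__(self, "centers_cm", centers)
        object.__setattr__(self, "ecc_deg", ecc)

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def center_location(self) -> int:
        """1-based row-major index of the Reference (centre) cell."""
        return (self.n_rows // 2) * self.n_cols + self.n_cols // 2 + 1

    @property
    def target_locations(self) -> tuple[int, ...]:
        """All candidate target locations (every cell except the centre)."""
        return tuple(i for i in range(1, self.n_cells + 1) if i != self.center_location)

    def location_of(self, col: int, row: int) -> int:
        """Map 1-based (col, row) to the 1-based row-major location index."""
        if not (1 <= col <= self.n_cols and 1 <= row <= self.n_rows):
            raise ValueError(f"cell (col={col}, row={row}) outside the grid")
        return (row - 1) * self.n_cols + col

    def col_row(self, location: int) -> tuple[int, int]:
        if not 1 <= location <= self.n_cells:
            raise ValueError(f"location index {location} outside 1..{self.n_cells}")
        return (location - 1) % self.n_cols + 1, (location - 1) // self.n_cols + 1

    def eccentricity(self, location: int) -> float:
        """Eccentricity of a cell centre in degrees of visual angle."""
        if not 1 <= location <= self.n_cells:
            raise ValueError(f"location index {location} outside 1..{self.n_cells}")
        return float(self.ecc_deg[location - 1])

    def refined_subset(self) -> tuple[int, ...]:
        """Location indices of the default refined 22-location protocol."""
        return tuple(self.location_of(c, r) for c, r in REFINED_22)

    def refinement_ladder(self) -> tuple[tuple[int, ...], ...]:
        """Nested location subsets of sizes 4, 12, 22 and 62 for the
        sparse-subset precision analysis."""
        refined = [self.location_of(c, r) for c, r in REFINED_22]
        return (tuple(refined[:4]), tuple(refined[:12]), tuple(refined),
                self.target_locations)


@dataclass(frozen=True)
class SearchSessionResult:
    """One simulated run of the search test."""

    trials: tuple[tuple[int, float], ...]  # (location index, RT seconds) in order
    per_location_rt: Mapping[int, float]
    median_rt: float
    seed: int | None = None

    def __post_init__(self) -> None:
        locs = [loc for loc, _ in self.trials]
        if len(set(locs)) != len(locs):
            raise ValueError("each scheduled location must appear exactly once")
        rts = np.array([rt for _, rt in self.trials])
        if np.any(rts <= 0):
            raise ValueError("response times must be positive")
        if abs(self.median_rt - float(np.median(rts))) > 1e-12:
            raise ValueError("median_rt must equal the median of the recorded RTs")


def build_grid(config: Mapping | None = None) -> SearchGrid:
    """Construct the search grid, optionally overriding geometry fields
    (n_cols, n_rows, screen_w_cm, screen_h_cm, viewing_distance_cm)."""
    return SearchGrid(**dict(config or {}))


def schedule_locations(
    grid: SearchGrid,
    subset: "str | Iterable[int]" = "all",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Seeded random order of target locations, each visited exactly once.

    ``subset`` is "all" (the 62 non-centre cells), "refined" (the default
    22-location protocol) or an explicit iterable of location indices that
    must exclude the centre cell.
    """
    if isinstance(subset, str):
        if subset == "all":
            locs = list(grid.target_locations)
        elif subset == "refined":
            locs = list(grid.refined_subset())
        else:
            raise ValueError("subset must be 'all', 'refined' or explicit locations")
    else:
        locs = [int(loc) for loc in subset]
        if len(set(locs)) != len(locs):
            raise ValueError("duplicate locations in subset")
        bad = [loc for loc in locs if not 1 <= loc <= grid.n_cells]
        if bad:
            raise ValueError(f"locations outside the grid: {bad}")
        if grid.center_location in locs:
            raise ValueError("the centre (Reference) cell can never be a target")
    if rng is None:
        rng = np.random.default_rng(seed)
    return [int(loc) for loc in rng.permutation(locs)]


def median_rt(rts: Sequence[float]) -> float:
    """Median response time (mean of the central pair for even counts)."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("cannot take the median of an empty RT set")
    return float(np.median(rts))


class SearchObserver(Protocol):
    """Anything that can produce an RT at a given eccentricity."""

    def search_rt(self, ecc_deg: float, rng: np.random.Generator) -> float: ...


def run_search_session(
    observer: SearchObserver,
    grid: SearchGrid | None = None,
    subset: "str | Iterable[int]" = "all",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SearchSessionResult:
    """Simulate one run of the search test over a scheduled location set.

    For each scheduled location the observer draws an RT at that location's
    eccentricity; the session summary is the median RT.  Reproducible given
    ``seed`` (or an explicit generator).
    """
    grid = grid or SearchGrid()
    if rng is None:
        rng = np.random.default_rng(seed)
    order = schedule_locations(grid, subset, rng=rng)
    trials = tuple(
        (loc, float(observer.search_rt(grid.eccentricity(loc), rng))) for loc in order
    )
    per_loc = {loc: rt for loc, rt in trials}
    return SearchSessionResult(
        trials=trials,
        per_location_rt=per_loc,
        median_rt=median_rt([rt for _, rt in trials]),
        seed=seed,
    )
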