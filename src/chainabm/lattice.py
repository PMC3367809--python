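"""The spatial substrate: a rectangular lattice of tri-state sites.

The migratory domain is a non-cyclic 150 x 45 grid (x: proximal-to-distal,
y: anterior-to-posterior) whose distal edge (max x) is the migratory
target.  Each site is 30 um wide, roughly one cell length.  Sites are
Closed until first occupied, Occupied while an agent sits on them, and
Open once the agent leaves — so moving agents leave open tracks of least
resistance in their wake.  A site never returns to Closed.
"""

from __future__ import annotations

import enum

import numpy as np

from . import _engine

SITE_WIDTH_UM = 30.0


class Direction(enum.IntEnum):
    """The eight compass moves (+x = distal, +y = posterior) plus NONE.

    Values 0..7 step counter-clockwise by 45 degrees starting from distal;
    NONE represents "no directional decision" and has no offset.
    """

    DISTAL = 0
    DISTAL_POSTERIOR = 1
    POSTERIOR = 2
    PROXIMAL_POSTERIOR = 3
    PROXIMAL = 4
    PROXIMAL_ANTERIOR = 5
    ANTERIOR = 6
    DISTAL_ANTERIOR = 7
    NONE = 8

    @property
    def offset(self) -> tuple[int, int]:
        if self is Direction.NONE:
            raise ValueError("Direction.NONE has no lattice offset")
        return int(_engine.DX[self]), int(_engine.DY[self])

    @property
    def opposite(self) -> "Direction":
        if self is Direction.NONE:
            return Direction.NONE
        return Direction((self + 4) % 8)


#: The eight movable directions, in compass order.
COMPASS = tuple(Direction(d) for d in range(8))


class SiteState(enum.IntEnum):
    CLOSED = _engine.CLOSED
    OPEN = _engine.OPEN
    OCCUPIED = _engine.OCCUPIED


_STATE_CHARS = {SiteState.CLOSED: "#", SiteState.OPEN: ".",
                SiteState.OCCUPIED: "@"}
_CHAR_STATES = {"#": SiteState.CLOSED, ".": SiteState.OPEN,
                "@": SiteState.OCCUPIED, "L": SiteState.OCCUPIED,
                "F": SiteState.OCCUPIED}


class Grid:
    """Tri-state site grid with the legal-transition discipline.

    Parameters
    ----------
    width, height : int
        Grid extent in sites; defaults give the 6750-site domain.
    site_width_um : float
        Physical side length of one site (30 um, about one cell).
    """

    def __init__(self, width: int = 150, height: int = 45,
                 site_width_um: float = SITE_WIDTH_UM,
                 _states: np.ndarray | None = None):
        if width < 2 or height < 1:
            raise ValueError("grid must be at least 2 x 1 sites")
        self.width = int(width)
        self.height = int(height)
        self.site_width_um = float(site_width_um)
        if _states is None:
            self.states = np.zeros((self.width, self.height), np.uint8)
        else:
            if _states.shape != (self.width, self.height):
                raise ValueError("state array shape mismatch")
            self.states = _states

    # -- coordinate algebra -------------------------------------------------
    def in_bounds(self, pos) -> bool:
        x, y = pos
        return 0 <= x < self.width and 0 <= y < self.height

    def neighbor(self, pos, d: Direction):
        """Adjacent coordinate in direction ``d``, or None past an edge.

        Boundaries are non-cyclic; asking with ``Direction.NONE`` is a
        caller logic error.
        """
        if d == Direction.NONE:
            raise ValueError("neighbor() requires a movable direction")
        dx, dy = Direction(d).offset
        dest = (pos[0] + dx, pos[1] + dy)
        return dest if self.in_bounds(dest) else None

    # -- site states --------------------------------------------------------
    def state(self, pos) -> SiteState:
        return SiteState(self.states[pos[0], pos[1]])

    def occupy(self, pos) -> None:
        """Place an agent on a Closed or Open site."""
        if self.state(pos) == SiteState.OCCUPIED:
            raise ValueError(f"site {pos} is already occupied")
        self.states[pos[0], pos[1]] = SiteState.OCCUPIED

    def init_track(self, chain_row: int, front_x: int) -> "Grid":
        """Open the pre-existing track: every site in the chain's row from
        the site distal to the front agent out to the distal edge."""
        if not 0 <= chain_row < self.height:
            raise ValueError("chain_row out of bounds")
        if front_x >= self.width - 1:
            raise ValueError("degenerate track: front agent at distal edge")
        self.states[front_x + 1:self.width, chain_row] = SiteState.OPEN
        return self

    def apply_move(self, origin, dest) -> "Grid":
        """Move an agent: the origin becomes Open, the destination
        Occupied.  An Occupied or out-of-bounds destination is a
        rule-engine bug and raises."""
        if self.state(origin) != SiteState.OCCUPIED:
            raise ValueError(f"no agent at origin {origin}")
        if not self.in_bounds(dest):
            raise ValueError(f"destination {dest} out of bounds")
        if self.state(dest) == SiteState.OCCUPIED:
            raise ValueError(f"destination {dest} already occupied")
        self.states[origin[0], origin[1]] = SiteState.OPEN
        self.states[dest[0], dest[1]] = SiteState.OCCUPIED
        return self

    # -- counts -------------------------------------------------------------
    def count(self, state: SiteState) -> int:
        return int(np.count_nonzero(self.states == int(state)))

    # -- plain-text raster --------------------------------------------------
    def to_text(self) -> str:
        """One character per site, one row of the grid per line (y down)."""
        rows = []
        for y in range(self.height):
            rows.append("".join(_STATE_CHARS[SiteState(self.states[x, y])]
                                for x in range(self.width)))
        return "\n".join(rows)

    @classmethod
    def from_text(cls, text: str, site_width_um: float = SITE_WIDTH_UM):
        """Read a raster produced by :meth:`to_text` (agent glyphs such as
        ``L``/``F`` read back as Occupied)."""
        lines = [ln for ln in text.splitlines() if ln]
        height = len(lines)
        width = len(lines[0])
        if any(len(ln) != width for ln in lines):
            raise ValueError("ragged raster")
        grid = cls(width, height, site_width_um)
        for y, ln in enumerate(lines):
            for x, ch in enumerate(ln):
                try:
                    grid.states[x, y] = _CHAR_STATES[ch]
                except KeyError:
                    raise ValueError(f"unknown raster character {ch!r}")
        return grid

    def __eq__(self, other):
        return (isinstance(other, Grid)
                and self.width == other.width
                and self.height == other.height
                and bool(np.array_equal(self.states, other.states)))

    def __repr__(self):
        return (f"Grid({self.width}x{self.height}, "
                f"occupied={self.count(SiteState.OCCUPIED)}, "
                f"open={self.count(SiteState.OPEN)})")
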