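"""Level 2 — opponent-motion detectors (expansion, contraction, rotation).

Opponent motion is locally antagonistic structure in the flow field:
horizontal/vertical expansion and contraction, plus clockwise and
counterclockwise rotation.  Each detector pools the level-1 direction maps
over a few large, overlapping subfields by maximum (conferring positional
invariance within the receptive field) and then combines the subfield
signals with the opponency rule of its kind: a conjunction (soft AND, the
minimum by default) of the two motion components that define the pattern.

Default layout: 4 expansion/contraction kinds x (5 x 4) assemblies = 80
detectors, plus 10 clockwise and 10 counterclockwise rotation detectors
(5 x 2 assemblies each), for 100 detectors in total.  A config variant
(``rotation_assemblies=4``) doubles the rotation population to 40.

A rotation detector has four contiguous, overlapping subfields (upper-left,
upper-right, lower-left, lower-right).  Because level 1 only signals the
four cardinal directions, rotation is detected through either of two
conditions — for clockwise: (A) upper subfields moving right AND lower
subfields moving left, or (B) left subfields moving up AND right subfields
moving down; either condition alone triggers the detector (maximum across
conditions).  Counterclockwise mirrors the signs, so an x-reflection of the
stimulus swaps the two senses exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motion_energy import DIRECTIONS, DirectionMaps

KINDS = ("h_expand", "h_contract", "v_expand", "v_contract", "cw", "ccw")

_R, _L, _U, _D = (DIRECTIONS.index(d) for d in ("right", "left", "up", "down"))


@dataclass(frozen=True)
class OpponentConfig:
    grid_rows: int = 36
    grid_cols: int = 31
    assembly_rows: int = 5  # detector positions per kind, vertical
    assembly_cols: int = 4  # ... horizontal, expansion/contraction kinds
    rotation_assemblies: int = 2  # horizontal positions of rotation kinds
    rf_rows: int = 12  # detector receptive-field extent in grid cells
    rf_cols: int = 13
    rotation_enabled: bool = True
    conjunction: str = "min"  # soft AND: "min" or "product"


@dataclass(frozen=True)
class Detector:
    kind: str
    row: int  # assembly row index
    col: int  # assembly column index
    #: subfield name -> (row slice, col slice) into the 36 x 31 grid
    subfields: dict = field(default_factory=dict)


@dataclass
class OpponentLayout:
    detectors: list
    config: OpponentConfig

    @property
    def n_detectors(self) -> int:
        return len(self.detectors)

    def kind_slice(self, kind: str) -> slice:
        idx = [i for i, d in enumerate(self.detectors) if d.kind == kind]
        return slice(idx[0], idx[-1] + 1) if idx else slice(0, 0)


def _positions(n: int, extent: int, size: int) -> list[int]:
    """n start offsets of size-``size`` windows spanning [0, extent],
    symmetric under reflection of the axis."""
    if n == 1:
        return [(extent - size) // 2]
    span = extent - size
    pos = [round(i * span / (n - 1)) for i in range(n)]
    # enforce reflection symmetry: start[i] = extent - size - start[n-1-i]
    return [(p + (extent - size - pos[n - 1 - i])) // 2
            for i, p in enumerate(pos)]


def _halves(n: int) -> tuple[slice, slice]:
    """Two contiguous, overlapping halves of an n-cell extent."""
    cut = (n + 1) // 2
    return slice(0, cut), slice(n - cut, n)


def build_layout(rotation_enabled: bool | None = None,
                 config: OpponentConfig | None = None) -> OpponentLayout:
    """Construct the opponent-detector layout over the level-1 grid.

    With the defaults this instantiates 100 detectors (80 expansion/
    contraction + 20 rotation); ``rotation_enabled=False`` gives the
    80-detector variant.  Detectors are ordered by (kind, assembly row,
    assembly column) with kind order ``KINDS``, so the first 80 components
    of the feature vector are identical whether or not rotation is enabled.
    """
    config = config or OpponentConfig()
    if rotation_enabled is not None:
        config = OpponentConfig(**{**config.__dict__,
                                   "rotation_enabled": rotation_enabled})
    if config.rf_rows > config.grid_rows or config.rf_cols > config.grid_cols:
        raise ValueError("detector receptive field exceeds the grid")
    row_pos = _positions(config.assembly_rows, config.grid_rows, config.rf_rows)
    col_pos = _positions(config.assembly_cols, config.grid_cols, config.rf_cols)
    rot_col_pos = _positions(config.rotation_assemblies, config.grid_cols,
                             config.rf_cols)
    rtop, rbot = _halves(config.rf_rows)
    cleft, cright = _halves(config.rf_cols)

    def shifted(sl: slice, off: int) -> slice:
        return slice(sl.start + off, sl.stop + off)

    detectors = []
    for kind in KINDS[:4]:
        for i, r0 in enumerate(row_pos):
            for j, c0 in enumerate(col_pos):
                full_r = slice(r0, r0 + config.rf_rows)
                full_c = slice(c0, c0 + config.rf_cols)
                if kind.startswith("h"):
                    subs = {"left": (full_r, shifted(cleft, c0)),
                            "right": (full_r, shifted(cright, c0))}
                else:
                    subs = {"upper": (shifted(rtop, r0), full_c),
                            "lower": (shifted(rbot, r0), full_c)}
                detectors.append(Detector(kind, i, j, subs))
    if config.rotation_enabled:
        for kind in KINDS[4:]:
            for i, r0 in enumerate(row_pos):
                for j, c0 in enumerate(rot_col_pos):
                    subs = {
                        "ul": (shifted(rtop, r0), shifted(cleft, c0)),
                        "ur": (shifted(rtop, r0), shifted(cright, c0)),
                        "ll": (shifted(rbot, r0), shifted(cleft, c0)),
                        "lr": (shifted(rbot, r0), shifted(cright, c0)),
                    }
                    detectors.append(Detector(kind, i, j, subs))
    for d in detectors:
        for (rs, cs) in d.subfields.values():
            if not (0 <= rs.start < rs.stop <= config.grid_rows
                    and 0 <= cs.start < cs.stop <= config.grid_cols):
                raise ValueError(f"subfield of {d.kind} out of grid bounds")
    return OpponentLayout(detectors, config)


@dataclass
class OpponentFeatureVector:
    """Activations of all opponent detectors for one frame pair."""

    values: np.ndarray
    frame_index: int
    rotation_enabled: bool


def _conj(a, b, op: str):
    return np.minimum(a, b) if op == "min" else a * b


def _sub_max(maps: np.ndarray, sub, channel: int) -> float:
    rs, cs = sub
    return float(np.max(maps[rs, cs, channel]))


def rotation_condition(subfields, sense: str, op: str = "min") -> float:
    """Rotation activation from four subfield direction tuples.

    ``subfields`` maps 'ul'/'ur'/'ll'/'lr' to (right, left, up, down)
    signal tuples.  Within a condition the two required components combine
    conjunctively (min by default); the two alternative conditions combine
    disjunctively (max).
    """
    ul, ur, ll, lr = (np.asarray(subfields[k], dtype=float)
                      for k in ("ul", "ur", "ll", "lr"))
    if sense == "cw":
        cond_a = _conj(max(ul[_R], ur[_R]), max(ll[_L], lr[_L]), op)
        cond_b = _conj(max(ul[_U], ll[_U]), max(ur[_D], lr[_D]), op)
    elif sense == "ccw":
        cond_a = _conj(max(ul[_L], ur[_L]), max(ll[_R], lr[_R]), op)
        cond_b = _conj(max(ul[_D], ll[_D]), max(ur[_U], lr[_U]), op)
    else:
        raise ValueError("sense must be 'cw' or 'ccw'")
    return float(max(cond_a, cond_b))


def opponent_response(maps: DirectionMaps,
                      layout: OpponentLayout) -> OpponentFeatureVector:
    """Evaluate every detector on one frame pair's direction maps."""
    m = maps.maps
    if m.shape[:2] != (layout.config.grid_rows, layout.config.grid_cols):
        raise ValueError("direction maps do not match the layout's grid")
    op = layout.config.conjunction
    vals = np.empty(layout.n_detectors)
    for n, det in enumerate(layout.detectors):
        s = det.subfields
        if det.kind == "h_expand":
            vals[n] = _conj(_sub_max(m, s["left"], _L),
                            _sub_max(m, s["right"], _R), op)
        elif det.kind == "h_contract":
            vals[n] = _conj(_sub_max(m, s["left"], _R),
                            _sub_max(m, s["right"], _L), op)
        elif det.kind == "v_expand":
            vals[n] = _conj(_sub_max(m, s["upper"], _U),
                            _sub_max(m, s["lower"], _D), op)
        elif det.kind == "v_contract":
            vals[n] = _conj(_sub_max(m, s["upper"], _D),
                            _sub_max(m, s["lower"], _U), op)
        else:
            subs = {k: tuple(np.max(m[rs, cs, d] )
                             for d in range(4))
                    for k, (rs, cs) in s.items()}
            vals[n] = rotation_condition(subs, det.kind, op)
    return OpponentFeatureVector(vals, maps.frame_index,
                                 layout.config.rotation_enabled)


def feature_matrix(maps_seq, layout: OpponentLayout) -> np.ndarray:
    """Stack per-frame-pair feature vectors into an (n_pairs, n_det) array."""
    return np.stack([opponent_response(m, layout).values for m in maps_seq])
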