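"""Channel geometry: hemispheres, homologous pairs and regions of interest.

A montage describes which source–detector pairs form channels, which channel
on the opposite hemisphere mirrors each channel, and which channel sets make
up the named regions of interest used by the laterality analysis:

* ``language`` — inferior-frontal coverage: left channels 43, 44, 46, 47 and
  their right-hemisphere homologs 34, 35, 38, 39;
* ``attention`` — parietal (IPS/SPL) coverage: right channels 60, 62, 63, 64
  and their left-hemisphere homologs 7, 10, 11, 13.

The instrument's optode geometry is not public, so :func:`default_montage`
builds a synthetic but deterministic layout that reproduces the channel
count, the numbering of the ROI channels and their mirror pairing; nothing
downstream depends on physical positions beyond left/right membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Mirror pairs fixed by the ROI definitions (left id, right id).
_ROI_PAIRS_LANGUAGE = [(43, 34), (44, 35), (46, 38), (47, 39)]
_ROI_PAIRS_ATTENTION = [(7, 60), (10, 62), (11, 63), (13, 64)]


@dataclass(frozen=True)
class ChannelDef:
    channel_id: int
    source_id: int
    detector_id: int
    hemisphere: str  # "left" | "right" | "midline"


@dataclass
class Montage:
    """Optode/channel layout with homology and ROI structure.

    Invariants (checked on construction): ``homolog_map`` is a symmetric
    bijection between left and right channels; each ROI's left and right
    sets are homolog images of each other; ``separation_cm`` > 0.
    """

    sources: list[int]
    detectors: list[int]
    channels: list[ChannelDef]
    homolog_map: dict[int, int]
    roi_defs: dict[str, dict[str, set[int]]]
    separation_cm: float = 3.0
    optode_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("channel ids must be unique")
        if self.separation_cm <= 0:
            raise ValueError("separation_cm must be positive")
        hemi = self.hemisphere_of
        for a, b in self.homolog_map.items():
            if self.homolog_map.get(b) != a:
                raise ValueError(f"homolog_map not symmetric at {a}<->{b}")
            if a != b and {hemi[a], hemi[b]} != {"left", "right"}:
                raise ValueError(f"homolog pair {a}<->{b} not cross-hemispheric")
        for name, sides in self.roi_defs.items():
            left, right = set(sides["left"]), set(sides["right"])
            if len(left) != len(right):
                raise ValueError(f"ROI {name!r}: unequal left/right cardinality")
            if {self.homolog_map[c] for c in left} != right:
                raise ValueError(f"ROI {name!r}: sides are not homolog images")

    @property
    def channel_ids(self) -> list[int]:
        return [c.channel_id for c in self.channels]

    @property
    def hemisphere_of(self) -> dict[int, str]:
        return {c.channel_id: c.hemisphere for c in self.channels}

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def roi_channels(self, roi: str, side: str) -> list[int]:
        return sorted(self.roi_defs[roi][side])


def _default_roi_defs() -> dict[str, dict[str, set[int]]]:
    return {
        "language": {
            "left": {l for l, _ in _ROI_PAIRS_LANGUAGE},
            "right": {r for _, r in _ROI_PAIRS_LANGUAGE},
        },
        "attention": {
            "left": {l for l, _ in _ROI_PAIRS_ATTENTION},
            "right": {r for _, r in _ROI_PAIRS_ATTENTION},
        },
    }


def default_montage(n_channels: int = 80) -> Montage:
    """Build the default synthetic montage.

    Parameters
    ----------
    n_channels : {80, 16}
        80 gives the full-head layout (24 sources, 30 detectors); 16 gives a
        reduced layout containing exactly the two ROIs and their homologs,
        convenient for fast simulation studies.
    """
    fixed_pairs = _ROI_PAIRS_LANGUAGE + _ROI_PAIRS_ATTENTION
    if n_channels == 16:
        pairs = fixed_pairs
        n_src, n_det = 16, 16
    elif n_channels == 80:
        used = {c for p in fixed_pairs for c in p}
        rest = [c for c in range(1, 81) if c not in used]
        pairs = fixed_pairs + list(zip(rest[:32], rest[32:]))
        n_src, n_det = 24, 30
    else:
        raise ValueError("n_channels must be 80 or 16")

    half_src, half_det = n_src // 2, n_det // 2
    channels: list[ChannelDef] = []
    positions: dict[str, np.ndarray] = {}
    homolog: dict[int, int] = {}
    for k, (left_id, right_id) in enumerate(sorted(pairs)):
        s, d = k % half_src, k % half_det
        channels.append(ChannelDef(left_id, 1 + s, 1 + d, "left"))
        channels.append(ChannelDef(right_id, 1 + half_src + s, 1 + half_det + d, "right"))
        homolog[left_id] = right_id
        homolog[right_id] = left_id
    channels.sort(key=lambda c: c.channel_id)

    # Mirror-symmetric optode grid: x<0 left, x>0 right (cm). Positions are
    # only carried through to file output; analyses use ids and hemispheres.
    for s in range(half_src):
        positions[f"S{1 + s}"] = np.array([-6.0, 2.0 * s, 0.0])
        positions[f"S{1 + half_src + s}"] = np.array([6.0, 2.0 * s, 0.0])
    for d in range(half_det):
        positions[f"D{1 + d}"] = np.array([-3.0, 2.0 * d, 0.0])
        positions[f"D{1 + half_det + d}"] = np.array([3.0, 2.0 * d, 0.0])

    return Montage(
        sources=list(range(1, n_src + 1)),
        detectors=list(range(1, n_det + 1)),
        channels=channels,
        homolog_map=homolog,
        roi_defs=_default_roi_defs(),
        separation_cm=3.0,
        optode_positions=positions,
    )
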