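"""Cuboid synapse geometry.

The computational domain is a box: a slab of presynaptic cell, its
membrane, the thin extracellular sheet between the cells, the postsynaptic
membrane, and a slab of postsynaptic cell, stacked along y (the
cleft-normal axis).  The central l_ix x l_iz part of the extracellular
sheet is the synaptic cleft proper (restricted diffusion); beyond its edge
the sheet continues as unrestricted extracellular space to the domain
boundary, where the extracellular reservoir conditions are imposed.
Everything is centered laterally at x = z = 0; y runs from 0 (outer
presynaptic boundary) to the outer postsynaptic boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Geometry"]


@dataclass(frozen=True)
class Geometry:
    """Synapse geometry, all lengths in nm.

    Attributes
    ----------
    h : cleft height (membrane-to-membrane distance).
    l_m : membrane thickness.
    w_a : side of the square AMPA-receptor area on the postsynaptic membrane.
    w_v : side of the (cubic) synaptic vesicle.
    w_vo : side of the square vesicle opening through the presynaptic
        membrane.
    l_ex, l_ez : total domain extent in x and z (the extracellular sheet
        reaches the domain boundary).
    l_ix, l_iz : lateral extent of the synaptic cleft proper (total cleft
        width, the region with restricted diffusion).
    l_iy : depth of each cell slab in y.
    """

    h: float = 15.0
    l_m: float = 5.0
    w_a: float = 140.0
    w_v: float = 40.0
    w_vo: float = 4.0
    l_ex: float = 1000.0
    l_ez: float = 1000.0
    l_ix: float = 600.0
    l_iz: float = 600.0
    l_iy: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("h", "l_m", "w_a", "w_v", "w_vo", "l_ex", "l_ez",
                     "l_ix", "l_iz", "l_iy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"geometry length {name!r} must be positive")
        if self.w_vo >= self.w_v:
            raise ValueError("vesicle opening w_vo must be smaller than the vesicle w_v")
        if self.w_a >= self.l_ix or self.w_a >= self.l_iz:
            raise ValueError("AMPA area w_a must fit inside the cleft lateral extent")
        if self.w_v >= self.l_ix or self.w_v >= self.l_iz:
            raise ValueError("vesicle must fit laterally inside the cell")
        if self.w_v >= self.l_iy:
            raise ValueError("vesicle must fit inside the presynaptic cell depth")
        if self.l_ix >= self.l_ex or self.l_iz >= self.l_ez:
            raise ValueError(
                "the cleft must be narrower than the extracellular sheet")

    # -- derived y stations (presynaptic side at y = 0) -------------------
    @property
    def y_pre_membrane(self) -> tuple[float, float]:
        """y-range of the presynaptic membrane."""
        return (self.l_iy, self.l_iy + self.l_m)

    @property
    def y_cleft(self) -> tuple[float, float]:
        """y-range of the synaptic cleft."""
        a = self.l_iy + self.l_m
        return (a, a + self.h)

    @property
    def y_post_membrane(self) -> tuple[float, float]:
        """y-range of the postsynaptic membrane."""
        a = self.l_iy + self.l_m + self.h
        return (a, a + self.l_m)

    @property
    def y_total(self) -> float:
        """Total domain extent in y."""
        return 2.0 * self.l_iy + 2.0 * self.l_m + self.h

    @property
    def y_vesicle(self) -> tuple[float, float]:
        """y-range of the vesicle (flush against the presynaptic membrane)."""
        return (self.l_iy - self.w_v, self.l_iy)

    @property
    def cleft_aspect_ratio(self) -> float:
        """Lateral cleft width over cleft height (l_ix / h)."""
        return self.l_ix / self.h

    @property
    def vesicle_volume(self) -> float:
        """Analytic vesicle volume, nm^3."""
        return self.w_v ** 3
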