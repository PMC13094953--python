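"""Clarke Error Grid classification for vital-sign agreement.

A scatter of measured (device) against reference (nurse) values is
partitioned into zones A-E of increasing clinical risk: A = clinically
accurate, B = benign error, C = error prompting unnecessary treatment,
D = dangerous failure to detect an abnormality, E = error that would
confuse treatment (opposite-direction abnormality).

Zone geometry is declarative: each zone is a polygonal region of the
(reference, measured) plane and the zones partition the domain rectangle.
The default geometry shipped here is built per parameter from

* an accuracy band around the identity line for zone A
  (``max(rel * reference, abs)`` half-width),
* a wider benign band plus the "both readings normal" and "both readings
  abnormal in the same direction" regions for zone B,
* normal/abnormal wedges for C (measured abnormal, reference normal),
  D (reference abnormal, measured normal) and E (opposite abnormality),

with per-parameter normal-range cutpoints.  These boundaries are a
reasoned default, not a published standard, and every report embeds the
geometry actually used.  Boundary points are assigned to the more benign
zone (A > B > C > D > E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box, mapping, shape
from shapely.ops import unary_union

from .core import Parameter

__all__ = [
    "ZoneConfig",
    "ZoneSummary",
    "default_zone_config",
    "default_zone_configs",
    "classify_clarke",
    "validate_zone_config",
]

ZONE_ORDER = ("A", "B", "C", "D", "E")
_TOL = 1e-9


@dataclass
class ZoneConfig:
    """Zone geometry for one parameter.

    ``zones`` maps labels to shapely geometries; classification walks the
    labels in benignity order so shared boundaries fall to the more benign
    zone.  ``domain`` is the plausible (lo, hi) range on both axes.
    """

    parameter: str
    domain: tuple[float, float]
    zones: dict[str, object] = field(default_factory=dict)

    def classify_point(self, reference: float, measured: float) -> tuple[str, bool]:
        """Zone label for one (reference, measured) pair.

        Returns ``(label, clamped)``; out-of-domain points are clamped to
        the domain rectangle, assigned the nearest zone, and reported as
        clamped so callers can log them.
        """
        lo, hi = self.domain
        clamped = not (lo <= reference <= hi and lo <= measured <= hi)
        r = min(max(reference, lo), hi)
        m = min(max(measured, lo), hi)
        pt = Point(r, m)
        for label in ZONE_ORDER:
            geom = self.zones.get(label)
            if geom is not None and geom.distance(pt) <= _TOL:
                return label, clamped
        # numerically safe fallback: nearest zone
        best = min(
            (lab for lab in ZONE_ORDER if lab in self.zones),
            key=lambda lab: self.zones[lab].distance(pt),
        )
        return best, clamped

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "domain": list(self.domain),
            "zones": {lab: mapping(geom) for lab, geom in self.zones.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZoneConfig":
        return cls(
            parameter=d["parameter"],
            domain=(float(d["domain"][0]), float(d["domain"][1])),
            zones={lab: shape(g) for lab, g in d["zones"].items()},
        )


@dataclass
class ZoneSummary:
    """Per-zone counts and proportions for one parameter."""

    parameter: str
    counts: dict[str, int]
    n_clamped: int = 0

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        n = self.n
        return {lab: (self.counts.get(lab, 0) / n if n else 0.0) for lab in ZONE_ORDER}

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "n": self.n,
            "counts": {lab: self.counts.get(lab, 0) for lab in ZONE_ORDER},
            "pct": {lab: round(100.0 * p, 1) for lab, p in self.proportions.items()},
            "n_clamped": self.n_clamped,
        }


# ---------------------------------------------------------------------------
# Default geometry
# ---------------------------------------------------------------------------

#: (relative half-width, absolute half-width) of the zone A band, the wider
#: zone B band, and the (low, high) normal-range cutpoints per parameter.
#: ``None`` for a cutpoint means no abnormality in that direction.
_DEFAULTS: dict[Parameter, dict] = {
    Parameter.MBP: dict(domain=(20.0, 180.0), a=(0.10, 5.0), b=(0.20, 10.0),
                        low=60.0, high=110.0),
    Parameter.PR: dict(domain=(20.0, 200.0), a=(0.10, 5.0), b=(0.20, 10.0),
                       low=50.0, high=110.0),
    Parameter.RR: dict(domain=(0.0, 60.0), a=(0.10, 3.0), b=(0.25, 5.0),
                       low=8.0, high=20.0),
    Parameter.SPO2: dict(domain=(50.0, 100.0), a=(0.0, 3.0), b=(0.0, 6.0),
                         low=90.0, high=None),
    Parameter.TEMP: dict(domain=(33.0, 42.0), a=(0.0, 0.5), b=(0.0, 1.0),
                         low=36.0, high=38.5),
}


def _band(domain: tuple[float, float], rel: float, absolute: float) -> Polygon:
    """Polygon around the identity line with half-width max(rel*r, abs)."""
    lo, hi = domain
    xs = [lo, hi]
    if rel > 0 and lo < absolute / rel < hi:
        xs.insert(1, absolute / rel)  # kink where the relative width takes over
    half = [max(rel * x, absolute) for x in xs]
    upper = [(x, x + h) for x, h in zip(xs, half)]
    lower = [(x, x - h) for x, h in zip(xs, half)]
    return Polygon(upper + list(reversed(lower)))


def default_zone_config(parameter: Parameter) -> ZoneConfig:
    """Construct the default zone partition for one parameter."""
    spec = _DEFAULTS[parameter]
    lo, hi = spec["domain"]
    dom = box(lo, lo, hi, hi)
    low_cut = spec["low"]
    high_cut = spec["high"] if spec["high"] is not None else hi

    band_a = _band((lo, hi), *spec["a"]).intersection(dom)
    band_b = _band((lo, hi), *spec["b"]).intersection(dom)

    # normal strips on each axis
    ref_normal = box(low_cut, lo, high_cut, hi).intersection(dom)
    meas_normal = box(lo, low_cut, hi, high_cut).intersection(dom)
    both_normal = ref_normal.intersection(meas_normal)
    both_low = box(lo, lo, low_cut, low_cut).intersection(dom)
    both_high = box(high_cut, high_cut, hi, hi).intersection(dom)

    zone_a = band_a
    zone_b = unary_union([band_b, both_normal, both_low, both_high]).difference(zone_a)
    remainder = dom.difference(zone_a).difference(zone_b)
    ref_abnormal = dom.difference(ref_normal)
    zone_d = remainder.intersection(ref_abnormal.intersection(meas_normal))
    zone_c = remainder.intersection(ref_normal.intersection(dom.difference(meas_normal)))
    zone_e = remainder.difference(zone_c).difference(zone_d)

    zones = {"A": zone_a, "B": zone_b, "C": zone_c, "D": zone_d, "E": zone_e}
    # drop degenerate slivers
    zones = {lab: g for lab, g in zones.items() if g.area > _TOL}
    return ZoneConfig(parameter=parameter.value, domain=(lo, hi), zones=zones)


def default_zone_configs() -> dict[str, ZoneConfig]:
    return {p.value: default_zone_config(p) for p in _DEFAULTS}


# ---------------------------------------------------------------------------
# Classification and validation
# ---------------------------------------------------------------------------


def classify_clarke(
    pairs: pd.DataFrame, zone_config: ZoneConfig
) -> tuple[pd.DataFrame, ZoneSummary]:
    """Assign each matched pair of one parameter to a zone.

    Reference = nurse value, measured = device value.  Returns the pair
    table with a ``zone`` column plus a :class:`ZoneSummary`.
    """
    sub = pairs.loc[pairs["parameter"] == zone_config.parameter].copy()
    labels: list[str] = []
    n_clamped = 0
    for nurse_v, device_v in zip(sub["nurse_value"], sub["device_value"]):
        lab, clamped = zone_config.classify_point(float(nurse_v), float(device_v))
        labels.append(lab)
        n_clamped += clamped
    sub["zone"] = labels
    counts = {lab: labels.count(lab) for lab in ZONE_ORDER}
    return sub, ZoneSummary(zone_config.parameter, counts, n_clamped)


def validate_zone_config(
    zone_config: ZoneConfig, probe_points: int = 10_000
) -> dict:
    """Check the partition, identity-in-A and ordering invariants.

    Probes a ``sqrt(n) x sqrt(n)`` lattice over the domain: every point
    must fall in exactly one zone (boundary ties to the more benign zone);
    any gap or interior overlap raises ``ValueError`` with a witness point.
    Returns diagnostics including the area share per zone.
    """
    lo, hi = zone_config.domain
    side = int(np.sqrt(probe_points))
    axis = np.linspace(lo, hi, side)

    # pairwise interior overlaps
    labs = [lab for lab in ZONE_ORDER if lab in zone_config.zones]
    for i, la in enumerate(labs):
        for lb in labs[i + 1:]:
            inter = zone_config.zones[la].intersection(zone_config.zones[lb])
            if inter.area > 1e-6:
                w = inter.representative_point()
                raise ValueError(
                    f"zones {la} and {lb} overlap; witness point "
                    f"({w.x:.4g}, {w.y:.4g})"
                )

    # coverage on the probe lattice
    for r in axis:
        for m in axis:
            pt = Point(r, m)
            hits = [lab for lab in labs
                    if zone_config.zones[lab].distance(pt) <= 1e-7]
            if not hits:
                raise ValueError(
                    f"partition gap: point ({r:.4g}, {m:.4g}) lies in no zone"
                )

    # identity line wholly in zone A
    for r in axis:
        lab, _ = zone_config.classify_point(r, r)
        if lab != "A":
            raise ValueError(
                f"identity point ({r:.4g}, {r:.4g}) classified as {lab}, not A"
            )

    total = (hi - lo) ** 2
    return {
        "parameter": zone_config.parameter,
        "valid": True,
        "area_share": {
            lab: zone_config.zones[lab].area / total for lab in labs
        },
    }


def clarke_plot(zone_config: ZoneConfig, pairs: pd.DataFrame | None = None, ax=None):
    """Draw the zone geometry and, optionally, the classified pairs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"A": "#c7e9c0", "B": "#fee391", "C": "#fdae6b",
              "D": "#fc9272", "E": "#de2d26"}
    for lab in ZONE_ORDER:
        geom = zone_config.zones.get(lab)
        if geom is None:
            continue
        polys = getattr(geom, "geoms", [geom])
        for poly in polys:
            if poly.is_empty or not hasattr(poly, "exterior"):
                continue
            xs, ys = poly.exterior.xy
            ax.fill(xs, ys, color=colors[lab], alpha=0.5, lw=0)
    if pairs is not None:
        sub = pairs.loc[pairs["parameter"] == zone_config.parameter]
        ax.scatter(sub["nurse_value"], sub["device_value"], s=10, color="k")
    lo, hi = zone_config.domain
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel(f"nurse (reference) {zone_config.parameter}")
    ax.set_ylabel(f"device (measured) {zone_config.parameter}")
    return ax
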