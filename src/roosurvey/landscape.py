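"""Landscape geometry and per-group landscape metrics.

A study landscape is a mosaic of cleared (grazing) polygons, each tagged
with a human-disturbance regime, embedded in a continuous forest matrix.
The metrics here quantify where animals sit relative to the forest edge
("cover"): distance to cover for points and group centres, the
front/behind positioning of vulnerable individuals (mothers, young-at-foot
and pouch young), grazing density per square kilometre of cleared habitat,
and relative green channel brightness ("greenness") of forage patches.

Coordinates are planar metres in a local frame; distances are Euclidean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, mapping, shape

#: The four human-disturbance regimes: High/Low frequency x Benign/Harm intent.
DISTURBANCE_LABELS = ("HB", "LB", "LH", "HH")

#: Six demographic size/maturity classes: large/medium/small adult,
#: sub-adult, young-at-foot, pouch young.
DEMO_CLASSES = ("LA", "MA", "SA", "SUB", "YAF", "PY")

ADULT_CLASSES = frozenset({"LA", "MA", "SA"})

M2_PER_HA = 10_000.0
M2_PER_KM2 = 1_000_000.0


class LandscapeError(ValueError):
    """Raised for invalid landscape geometry or points outside cleared habitat."""


@dataclass
class ClearedZone:
    """One cleared polygon with its disturbance tag."""

    label: str
    polygon: Polygon

    @property
    def area_ha(self) -> float:
        return self.polygon.area / M2_PER_HA

    @property
    def area_km2(self) -> float:
        return self.polygon.area / M2_PER_KM2


@dataclass
class Landscape:
    """Cleared zones surrounded by forest.

    The forest matrix is everything inside ``extent`` that is not cleared;
    the edge of a cleared polygon is therefore the forest edge, so the
    distance from a point inside a zone to cover is its distance to that
    zone's boundary.
    """

    zones: list[ClearedZone] = field(default_factory=list)
    extent: Polygon | None = None

    def zone_of(self, x: float, y: float) -> ClearedZone | None:
        p = Point(x, y)
        for z in self.zones:
            if z.polygon.covers(p):
                return z
        return None

    def zone(self, label: str) -> ClearedZone:
        for z in self.zones:
            if z.label == label:
                return z
        raise LandscapeError(f"no cleared zone labelled {label!r}")

    @property
    def forest(self) -> Polygon:
        """Forest matrix: the extent minus all cleared polygons."""
        if self.extent is None:
            raise LandscapeError("landscape has no extent; forest undefined")
        geom = self.extent
        for z in self.zones:
            geom = geom.difference(z.polygon)
        return geom

    # -- GeoJSON round trip ------------------------------------------------

    def to_geojson(self) -> dict:
        features = []
        for z in self.zones:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(z.polygon),
                    "properties": {
                        "class": "cleared",
                        "zone": z.label,
                        "area_ha": z.area_ha,
                    },
                }
            )
        if self.extent is not None:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(self.forest),
                    "properties": {"class": "forest", "zone": None,
                                   "area_ha": self.forest.area / M2_PER_HA},
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, obj: dict) -> "Landscape":
        zones = []
        forest_geoms = []
        for feat in obj.get("features", []):
            props = feat.get("properties", {})
            geom = shape(feat["geometry"])
            if props.get("class") == "cleared":
                zones.append(ClearedZone(label=props["zone"], polygon=geom))
            else:
                forest_geoms.append(geom)
        extent = None
        if forest_geoms:
            from shapely.ops import unary_union

            extent = unary_union(forest_geoms + [z.polygon for z in zones])
        return cls(zones=zones, extent=extent)

    @classmethod
    def load(cls, path) -> "Landscape":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


# ---------------------------------------------------------------------------
# Distance to cover
# ---------------------------------------------------------------------------

def distance_to_cover(x: float, y: float, landscape: Landscape) -> float:
    """Minimum distance (m) from a point in cleared habitat to the forest edge.

    Raises :class:`LandscapeError` if the point is not inside any cleared
    polygon (the diagnostic names the nearest zone).
    """
    zone = landscape.zone_of(x, y)
    if zone is None:
        p = Point(x, y)
        if landscape.zones:
            nearest = min(landscape.zones, key=lambda z: z.polygon.distance(p))
            raise LandscapeError(
                f"point ({x:.1f}, {y:.1f}) is outside cleared habitat "
                f"(nearest zone {nearest.label!r}, "
                f"{nearest.polygon.distance(p):.1f} m away)"
            )
        raise LandscapeError("point outside cleared habitat (landscape empty)")
    return zone.polygon.exterior.distance(Point(x, y))


# ---------------------------------------------------------------------------
# Vulnerable individuals and front/behind positioning
# ---------------------------------------------------------------------------

def identify_mothers(group: pd.DataFrame) -> pd.Series:
    """Boolean mask of mothers within one group.

    A mother is, operationally, an adult (LA/MA/SA) that carries an in-pouch
    young at its own coordinates, or the nearest adult to a young-at-foot in
    the same group.
    """
    is_mother = pd.Series(False, index=group.index)
    adults = group[group["demo_class"].isin(ADULT_CLASSES)]
    if adults.empty:
        return is_mother
    # adults with a coincident pouch young
    py = group[(group["demo_class"] == "PY") & (group.get("in_pouch", 1) == 1)]
    for _, row in py.iterrows():
        hit = adults[
            (adults["x_m"] == row["x_m"]) & (adults["y_m"] == row["y_m"])
        ]
        if not hit.empty:
            is_mother.loc[hit.index[0]] = True
    # nearest adult to each young-at-foot
    yaf = group[group["demo_class"] == "YAF"]
    ax = adults["x_m"].to_numpy()
    ay = adults["y_m"].to_numpy()
    for _, row in yaf.iterrows():
        d2 = (ax - row["x_m"]) ** 2 + (ay - row["y_m"]) ** 2
        is_mother.loc[adults.index[int(np.argmin(d2))]] = True
    return is_mother


def classify_positioning(
    group: pd.DataFrame, landscape: Landscape
) -> pd.DataFrame:
    """Front/behind classification of vulnerable individuals in one group.

    For each vulnerable member (mother, young-at-foot, pouch young) the
    record holds its individual distance to cover (IDC), the group-centre
    distance to cover (GDC, centre over out-of-pouch members), their
    difference ``delta = GDC - IDC`` and the side: ``front`` when delta > 0
    (the individual sits nearer the forest edge than the group centre),
    ``behind`` otherwise.  Exact ties (delta == 0) are classed ``behind``,
    the conservative choice for the front proportion.

    Returns an empty frame when the group has no vulnerable members.
    """
    out_of_pouch = group[group.get("in_pouch", 0) != 1]
    cx = out_of_pouch["x_m"].mean()
    cy = out_of_pouch["y_m"].mean()
    gdc = distance_to_cover(cx, cy, landscape)

    vulnerable = group["demo_class"].isin(("YAF", "PY")) | identify_mothers(group)
    records = []
    for idx, row in group[vulnerable].iterrows():
        idc = distance_to_cover(row["x_m"], row["y_m"], landscape)
        delta = gdc - idc
        records.append(
            {
                "individual_id": row.get("id", idx),
                "zone": row.get("zone"),
                "demo_class": row["demo_class"],
                "IDC": idc,
                "GDC": gdc,
                "delta": delta,
                "side": "front" if delta > 0 else "behind",
            }
        )
    cols = ["individual_id", "zone", "demo_class", "IDC", "GDC", "delta", "side"]
    return pd.DataFrame(records, columns=cols)


def positioning_proportions(
    records: pd.DataFrame, bracket_width: float = 20.0
) -> pd.DataFrame:
    """Front proportion per zone and per bracket of group distance to cover.

    Brackets are half-open intervals [0, w), [w, 2w), ... on GDC.  Empty
    zone x bracket cells are omitted.
    """
    if records.empty:
        raise ValueError("no positioning records supplied")
    rec = records.copy()
    rec["bracket"] = (rec["GDC"] // bracket_width).astype(int)
    rows = []
    for (zone, bracket), sub in rec.groupby(["zone", "bracket"]):
        n = len(sub)
        rows.append(
            {
                "zone": zone,
                "bracket": int(bracket),
                "bracket_lo_m": bracket * bracket_width,
                "prop_front": float((sub["side"] == "front").sum()) / n,
                "n": n,
            }
        )
    return pd.DataFrame(rows).sort_values(["zone", "bracket"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Grazing density
# ---------------------------------------------------------------------------

def grazing_density(
    observations: pd.DataFrame, landscape: Landscape
) -> pd.DataFrame:
    """Individuals per km2 of cleared habitat, per zone and session.

    All surveyed individuals count towards density, including those flagged
    as disturbed during the survey (they are excluded from grouping, not
    from density).  In-pouch young are individual observations and count.
    Zones or sessions with no observations get density 0.
    """
    sessions = sorted(observations["session"].unique())
    rows = []
    for z in landscape.zones:
        if z.area_km2 <= 0:
            raise LandscapeError(f"zone {z.label!r} has non-positive area")
        for s in sessions:
            n = int(
                ((observations["zone"] == z.label)
                 & (observations["session"] == s)).sum()
            )
            rows.append(
                {
                    "zone": z.label,
                    "session": s,
                    "count": n,
                    "area_km2": z.area_km2,
                    "density_per_km2": n / z.area_km2,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Greenness
# ---------------------------------------------------------------------------

@dataclass
class GreennessSample:
    """An RGB patch (H x W x 3) and its relative green channel brightness."""

    pixels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        self.pixels = arr

    @property
    def greenness(self) -> float:
        return greenness(self)


def greenness(sample: GreennessSample | np.ndarray) -> float:
    """Relative green channel brightness of an RGB patch.

    Sum of green digital numbers over all pixels divided by the summed
    brightness (R + G + B) over all pixels.  Lies in [0, 1] and is
    invariant to rescaling all three channels by one factor.  An all-black
    patch has no defined greenness and raises ``ValueError``.
    """
    arr = sample.pixels if isinstance(sample, GreennessSample) else np.asarray(sample)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.size == 0:
        raise ValueError("expected a non-empty (H, W, 3) RGB array")
    arr = arr.astype(np.float64)
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-black patch: total brightness is zero")
    return float(arr[..., 1].sum() / total)


def load_greenness_patch(path) -> GreennessSample:
    """Read a PNG/JPEG patch into a greenness sample (8-bit RGB)."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return GreennessSample(pixels=arr)
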