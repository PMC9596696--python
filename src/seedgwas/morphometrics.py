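"""The 34 named morphometric seed traits.

Traits are derived per view from the nine primitive measures of
:class:`~seedgwas.segmentation.ShapeGeometry`:

* **dorsal** (25 traits): the nine primitives plus 16 derived shape
  descriptors (aspect ratio, circularity, roundness, equivalent diameters,
  compactness, solidity, concavity, convexity, shape factor, R-factor,
  modification ratio, sphericity, Feret-aligned bounding box and
  rectangularity);
* **lateral** (4): Perim.1, Area.1, Thickness (the lateral Breadth) and
  ArBBox.1 = lateral Feret x Thickness;
* **vertical** (4): Perim.2, Area.2, ArBBox.2 = Breadth x Thickness and
  the ellipsoid Volume = (pi/6) Feret x Breadth x Thickness.

Circularity ships in two variants because published trait tables are not
always dimensionally consistent: ``table5`` is the dimensionless
4*pi*Area/Perim^2 (<= 1 by the isoperimetric inequality) and ``scaled`` is
4*pi*Area, an area-proportional quantity whose population mean equals
4*pi times the mean Area.  The default is ``table5``;
:func:`mean_consistency` works on the ``scaled`` convention.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DegenerateShape, MissingView
from .segmentation import ShapeGeometry

__all__ = [
    "DORSAL_TRAITS",
    "LATERAL_TRAITS",
    "VERTICAL_TRAITS",
    "ALL_TRAITS",
    "dorsal_traits",
    "lateral_traits",
    "vertical_traits",
    "seed_traits",
    "assemble_trait_table",
    "mean_consistency",
]

DORSAL_TRAITS = [
    "Perim", "Area", "MinR", "MaxR", "Feret", "Breadth", "CHull", "CArea",
    "MBCRadius", "AspRatio", "Circ", "Roundness", "ArEquivD", "PerEquivD",
    "EquivEllAr", "Compactness", "Solidity", "Concavity", "Convexity",
    "Shape", "RFactor", "ModRatio", "Sphericity", "ArBBox", "Rectang",
]
LATERAL_TRAITS = ["Perim.1", "Area.1", "ArBBox.1", "Thickness"]
VERTICAL_TRAITS = ["Perim.2", "Area.2", "ArBBox.2", "Volume"]
ALL_TRAITS = DORSAL_TRAITS + LATERAL_TRAITS + VERTICAL_TRAITS + ["TKW"]


def dorsal_traits(geom: ShapeGeometry, circ_variant: str = "table5") -> dict:
    """All 25 dorsal traits from one dorsal-view geometry."""
    if circ_variant not in ("table5", "scaled"):
        raise ValueError(f"unknown circ_variant {circ_variant!r}")
    A, P = geom.area, geom.perim
    F, B = geom.feret, geom.breadth
    if min(A, P, F, B, geom.carea, geom.max_r) <= 0:
        raise DegenerateShape("zero primitive measure in dorsal geometry")
    circ = 4.0 * math.pi * A / P**2 if circ_variant == "table5" else 4.0 * math.pi * A
    return {
        "Perim": P,
        "Area": A,
        "MinR": geom.min_r,
        "MaxR": geom.max_r,
        "Feret": F,
        "Breadth": B,
        "CHull": geom.chull,
        "CArea": geom.carea,
        "MBCRadius": geom.mbc_radius,
        "AspRatio": F / B,
        "Circ": circ,
        "Roundness": 4.0 * A / (math.pi * F**2),
        "ArEquivD": math.sqrt(4.0 / math.pi * A),
        "PerEquivD": A / math.pi,
        "EquivEllAr": math.pi * F * B / 4.0,
        "Compactness": math.sqrt(4.0 / math.pi * A) / F,
        "Solidity": A / geom.carea,
        "Concavity": geom.carea - A,
        "Convexity": geom.chull / P,
        "Shape": P**2 / A,
        "RFactor": geom.chull / (F * math.pi),
        "ModRatio": 2.0 * geom.min_r / F,
        "Sphericity": geom.min_r / geom.max_r,
        "ArBBox": F * B,
        "Rectang": A / (F * B),
    }


def lateral_traits(geom_lat: ShapeGeometry) -> dict:
    """Lateral-view traits; Thickness is the lateral Breadth and ArBBox.1
    pairs it with the *lateral* Feret."""
    if min(geom_lat.area, geom_lat.perim, geom_lat.feret, geom_lat.breadth) <= 0:
        raise DegenerateShape("zero primitive measure in lateral geometry")
    return {
        "Perim.1": geom_lat.perim,
        "Area.1": geom_lat.area,
        "Thickness": geom_lat.breadth,
        "ArBBox.1": geom_lat.feret * geom_lat.breadth,
    }


def vertical_traits(feret: float, breadth: float, thickness: float,
                    geom_vert: ShapeGeometry | None = None) -> dict:
    """Vertical-view traits plus the ellipsoid Volume.

    Volume needs only the dorsal Feret/Breadth and the lateral Thickness;
    Perim.2/Area.2 additionally need the vertical-view geometry and are
    returned as NaN when it is absent.
    """
    for name, val in (("Feret", feret), ("Breadth", breadth),
                      ("Thickness", thickness)):
        if val is None or not np.isfinite(val):
            raise MissingView(f"{name} unavailable; cannot derive vertical traits")
        if val <= 0:
            raise DegenerateShape(f"{name} must be > 0, got {val}")
    out = {
        "Perim.2": geom_vert.perim if geom_vert is not None else np.nan,
        "Area.2": geom_vert.area if geom_vert is not None else np.nan,
        "ArBBox.2": breadth * thickness,
        "Volume": math.pi / 6.0 * feret * breadth * thickness,
    }
    return out


def seed_traits(dorsal: ShapeGeometry,
                lateral: ShapeGeometry | None = None,
                vertical: ShapeGeometry | None = None,
                circ_variant: str = "table5") -> dict:
    """All image-derived traits of one seed; missing views yield NaNs."""
    rec: dict = {t: np.nan for t in DORSAL_TRAITS + LATERAL_TRAITS + VERTICAL_TRAITS}
    rec.update(dorsal_traits(dorsal, circ_variant))
    if lateral is not None:
        rec.update(lateral_traits(lateral))
        rec.update(vertical_traits(rec["Feret"], rec["Breadth"],
                                   rec["Thickness"], vertical))
    return rec


def assemble_trait_table(records: list[dict],
                         tkw: pd.DataFrame | None = None,
                         aggregate: bool = False) -> pd.DataFrame:
    """Stack per-seed trait records into a wide trait table.

    Each record must carry ``accession``, ``env``, ``rep`` and ``seed``
    keys alongside its trait values.  ``tkw`` (optional) is a frame with
    columns ``accession, env, rep, TKW`` joined by those keys — TKW is a
    weighed, per-accession quantity, not an image trait.  With
    ``aggregate=True`` seed-level rows are averaged per
    (accession, env, rep).
    """
    keys = ["accession", "env", "rep", "seed"]
    df = pd.DataFrame.from_records(records)
    missing = [k for k in keys if k not in df.columns]
    if missing:
        raise ValueError(f"records lack key columns {missing}")
    if df.duplicated(subset=keys).any():
        raise ValueError("duplicated (accession, env, rep, seed) keys")
    if aggregate:
        df = (df.drop(columns="seed")
                .groupby(["accession", "env", "rep"], as_index=False)
                .mean(numeric_only=True))
    if tkw is not None:
        on = ["accession", "env", "rep"]
        unmatched = set(map(tuple, df[on].drop_duplicates().itertuples(index=False))) \
            - set(map(tuple, tkw[on].itertuples(index=False)))
        if unmatched:
            raise ValueError(
                "TKW missing for keys: " + ", ".join(map(str, sorted(unmatched))))
        df = df.merge(tkw[on + ["TKW"]], on=on, how="left")
    return df


def mean_consistency(mean_area: float) -> tuple[float, float]:
    """Trait means implied by a mean Area through trait linearity.

    Both the scaled circularity (4*pi*Area) and PerEquivD (Area/pi) are
    linear in Area, so their population means follow from the mean Area
    alone: returns ``(4*pi*mean_area, mean_area/pi)``.
    """
    if mean_area < 0:
        raise ValueError("mean area must be >= 0")
    return 4.0 * math.pi * mean_area, mean_area / math.pi
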