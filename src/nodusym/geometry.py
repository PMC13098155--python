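"""Nodule volumes from 2-D section measurements.

Determinate (bean-type) nodules are treated as spheres: a longitudinal
section gives the section area ``A`` and Feret's diameters, from which the
sphere volume follows.  Indeterminate (pea-type) nodules are modelled as a
cylindrical body capped by an uninfected spherical cap at the distal end:
the cap is sized from the chord length ``c`` and sagitta ``h`` of its
circular segment, and the body as a cylinder of section area ``A`` and
midline length ``l_c`` (average width ``d = A / l_c``).

The infected volume ``V_i`` is obtained by scaling the infected-zone volume
``V_iz`` with the fractional colonization density ``f_c = A_i / A_iz``, the
fraction of infected-zone area actually occupied by fluorescent bacteroids.

Two conventions are deliberately exposed:

* ``convention`` for the sphere: ``"diameter"`` (default) treats Feret's
  diameter as a true diameter, ``V = (2/3) A F_d``; ``"radius"`` evaluates
  the literal form ``V = (4/3) A F_d``, which is a sphere formula only if
  ``F_d`` is a radius.
* ``chord_mode`` for the cap: ``"half_chord"`` (default) uses the textbook
  spherical-cap formula with base radius ``c/2``; ``"full_chord"``
  evaluates the literal ``V_c = (1/6) π h (3 c² + h²)``.

The defaults are the geometrically consistent forms (a hemisphere with
``h = r`` and ``c = 2r`` only returns ``(2/3) π r³`` under ``half_chord``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "BeanSectionMeasurement",
    "PeaSectionMeasurement",
    "NoduleVolumes",
    "sphere_volume_from_section",
    "cap_volume",
    "cylinder_volume",
    "colonization_fraction",
    "bean_nodule_volumes",
    "pea_nodule_volumes",
    "bean_volumes_table",
    "pea_volumes_table",
    "read_sections",
    "write_volumes",
]

BEAN_COLUMNS = ["A_nod", "F_dmax", "F_dmin", "A_iz", "F_dmax_iz", "F_dmin_iz", "A_i"]
PEA_COLUMNS = ["c", "h", "A_body", "l_c", "A_iz", "l_iz", "A_i"]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class BeanSectionMeasurement:
    """One longitudinal section of a spherical (determinate) nodule.

    Areas in mm², Feret's diameters in mm.  ``A_nod`` is the whole-nodule
    section area, ``A_iz`` the infected-zone area with its own Feret pair,
    and ``A_i`` the area covered by fluorescent (N2-fixing) bacteroids.
    """

    A_nod: float
    F_dmax: float
    F_dmin: float
    A_iz: float
    F_dmax_iz: float
    F_dmin_iz: float
    A_i: float

    def __post_init__(self) -> None:
        _require_positive(
            A_nod=self.A_nod,
            F_dmax=self.F_dmax,
            F_dmin=self.F_dmin,
            A_iz=self.A_iz,
            F_dmax_iz=self.F_dmax_iz,
            F_dmin_iz=self.F_dmin_iz,
        )
        if self.A_i < 0:
            raise ValueError("A_i must be non-negative")
        if not self.A_i <= self.A_iz <= self.A_nod:
            raise ValueError("expected A_i <= A_iz <= A_nod")
        if self.F_dmin > self.F_dmax:
            raise ValueError("F_dmin must not exceed F_dmax")


@dataclass(frozen=True)
class PeaSectionMeasurement:
    """One longitudinal section of a cylindrical (indeterminate) nodule.

    ``c``/``h`` are the chord and sagitta of the uninfected cap segment
    (mm); ``A_body``/``l_c`` the cylindrical body's section area (mm²) and
    midline length (mm); ``A_iz``/``l_iz`` the same pair for the infected
    zone; ``A_i`` the bacteroid-covered area (mm²).
    """

    c: float
    h: float
    A_body: float
    l_c: float
    A_iz: float
    l_iz: float
    A_i: float

    def __post_init__(self) -> None:
        _require_positive(c=self.c, h=self.h, A_body=self.A_body,
                          l_c=self.l_c, A_iz=self.A_iz, l_iz=self.l_iz)
        if self.A_i < 0:
            raise ValueError("A_i must be non-negative")
        if self.h > self.c:
            raise ValueError("sagitta h must not exceed chord c")
        if self.A_i > self.A_iz:
            raise ValueError("expected A_i <= A_iz")


@dataclass(frozen=True)
class NoduleVolumes:
    """Whole-nodule, infected-zone and infected volumes (mm³) plus f_c."""

    V_n: float
    V_iz: float
    f_c: float
    V_i: float
    host: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_c <= 1.0:
            raise ValueError("f_c must lie in [0, 1]")
        if not self.V_i <= self.V_iz * (1 + 1e-12):
            raise ValueError("expected V_i <= V_iz")


def sphere_volume_from_section(area: float, feret: float | tuple[float, float],
                               convention: str = "diameter") -> float:
    """Sphere volume (mm³) from a great-circle section area and Feret's diameter.

    For a true sphere of radius r, A = πr² and F_d = 2r, so
    V = (4/3)πr³ = (2/3)·A·F_d.  When both max and min Feret's diameters are
    supplied the mean of the two volume estimates is returned.
    """
    if isinstance(feret, tuple):
        return 0.5 * (sphere_volume_from_section(area, feret[0], convention)
                      + sphere_volume_from_section(area, feret[1], convention))
    _require_positive(area=area, feret=feret)
    if convention == "diameter":
        return (2.0 / 3.0) * area * feret
    if convention == "radius":
        return (4.0 / 3.0) * area * feret
    raise ValueError(f"unknown convention {convention!r}")


def cap_volume(c: float, h: float, chord_mode: str = "half_chord") -> float:
    """Spherical-cap volume (mm³) from chord length c and sagitta h.

    ``half_chord`` uses base radius a = c/2: V = (1/6)πh(3a² + h²).
    ``full_chord`` evaluates the same expression with c in place of a.
    """
    _require_positive(c=c, h=h)
    if chord_mode == "half_chord":
        a = c / 2.0
    elif chord_mode == "full_chord":
        a = c
    else:
        raise ValueError(f"unknown chord_mode {chord_mode!r}")
    return (math.pi / 6.0) * h * (3.0 * a * a + h * h)


def cylinder_volume(area: float, l_c: float) -> float:
    """Cylinder volume (mm³) from an axial section area and midline length.

    The average width is d = A/l_c; V = A·d·π/4 = (π/4)·A²/l_c, which is
    exact (π(d/2)²·l) for a rectangular axial section of a true cylinder.
    """
    _require_positive(area=area, l_c=l_c)
    return (math.pi / 4.0) * area * area / l_c


def colonization_fraction(a_i: float, a_iz: float) -> float:
    """Fractional colonization density f_c = A_i / A_iz, in [0, 1]."""
    if a_iz <= 0:
        raise ValueError("A_iz must be positive")
    if a_i < 0:
        raise ValueError("A_i must be non-negative")
    if a_i > a_iz:
        raise ValueError("A_i must not exceed A_iz")
    return a_i / a_iz


def bean_nodule_volumes(m: BeanSectionMeasurement,
                        convention: str = "diameter") -> NoduleVolumes:
    """Volumes of a spherical nodule from one section.

    V_n and V_iz use their own Feret pairs (max/min variants averaged after
    volume computation); V_i = V_iz · f_c.
    """
    v_n = sphere_volume_from_section(m.A_nod, (m.F_dmax, m.F_dmin), convention)
    v_iz = sphere_volume_from_section(m.A_iz, (m.F_dmax_iz, m.F_dmin_iz), convention)
    f_c = colonization_fraction(m.A_i, m.A_iz)
    return NoduleVolumes(V_n=v_n, V_iz=v_iz, f_c=f_c, V_i=v_iz * f_c, host="bean")


def pea_nodule_volumes(m: PeaSectionMeasurement,
                       chord_mode: str = "half_chord") -> NoduleVolumes:
    """Volumes of a cap + cylinder nodule from one section.

    V_n = V_c(c, h) + V_b(A_body, l_c); V_iz is the infected-zone cylinder;
    V_i = V_iz · f_c.
    """
    v_c = cap_volume(m.c, m.h, chord_mode)
    v_b = cylinder_volume(m.A_body, m.l_c)
    v_iz = cylinder_volume(m.A_iz, m.l_iz)
    f_c = colonization_fraction(m.A_i, m.A_iz)
    return NoduleVolumes(V_n=v_c + v_b, V_iz=v_iz, f_c=f_c, V_i=v_iz * f_c,
                         host="pea")


def _volumes_frame(rows: list[NoduleVolumes], ids) -> pd.DataFrame:
    out = pd.DataFrame({
        "nodule_id": ids,
        "V_n": [r.V_n for r in rows],
        "V_iz": [r.V_iz for r in rows],
        "f_c": [r.f_c for r in rows],
        "V_i": [r.V_i for r in rows],
        "host": [r.host for r in rows],
    })
    return out


def bean_volumes_table(df: pd.DataFrame, convention: str = "diameter") -> pd.DataFrame:
    """Apply :func:`bean_nodule_volumes` to every row of a section table."""
    missing = [c for c in BEAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bean section table missing columns: {missing}")
    rows = [bean_nodule_volumes(
        BeanSectionMeasurement(**{c: row[c] for c in BEAN_COLUMNS}), convention)
        for _, row in df.iterrows()]
    ids = df["nodule_id"] if "nodule_id" in df.columns else range(len(df))
    return _volumes_frame(rows, list(ids))


def pea_volumes_table(df: pd.DataFrame, chord_mode: str = "half_chord") -> pd.DataFrame:
    """Apply :func:`pea_nodule_volumes` to every row of a section table."""
    missing = [c for c in PEA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pea section table missing columns: {missing}")
    rows = [pea_nodule_volumes(
        PeaSectionMeasurement(**{c: row[c] for c in PEA_COLUMNS}), chord_mode)
        for _, row in df.iterrows()]
    ids = df["nodule_id"] if "nodule_id" in df.columns else range(len(df))
    return _volumes_frame(rows, list(ids))


def read_sections(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_volumes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
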