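"""Density-mapped isotropic elastic material model for bone FE meshes.

Cancellous bone gets its Young's modulus from the empirical power law

    E [GPa] = 0.001 * rho^1.3266,   rho in kg/m^3,

optionally rounded to the nearest 0.5 GPa to acknowledge the uncertainty of the
regression, with a fixed Poisson's ratio of 0.3.  Cortical bone is assigned fixed
literature values (rho = 2.06 g/cm^3, E = 20,000 MPa, nu = 0.4) rather than the
regression — the power law was fitted to cancellous data and under-predicts the
modulus of compact bone.

Interfaces use g/cm^3 and MPa (the conventional units of bone-FE material
tables); conversions are kept in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialCard",
    "REGRESSION_A",
    "REGRESSION_B",
    "CORTICAL",
    "density_to_modulus",
    "homogenize",
    "total_mass",
    "default_cancellous_card",
    "reference_table",
]

REGRESSION_A = 0.001  # GPa per (kg/m^3)^b
REGRESSION_B = 1.3266
NU_CANCELLOUS = 0.3

#: fixed cortical-bone properties (modal literature values, not the regression)
CORTICAL = {"rho": 2.06, "E": 20000.0, "nu": 0.4}


def density_to_modulus(rho: float, round_half_gpa: bool = True) -> float:
    """Young's modulus (MPa) of cancellous bone of apparent density `rho` (g/cm^3).

    Evaluates E = 0.001 * (1000 rho)^1.3266 GPa and, when `round_half_gpa`,
    rounds to the nearest 0.5 GPa before converting to MPa.
    """
    if rho <= 0:
        raise ValueError("density must be positive")
    e_gpa = REGRESSION_A * (1000.0 * rho) ** REGRESSION_B
    if round_half_gpa:
        e_gpa = np.floor(e_gpa * 2.0 + 0.5) / 2.0
    return float(e_gpa * 1000.0)


def homogenize(class_densities, class_volumes) -> float:
    """Volume-weighted mean density (g/cm^3) of a set of material classes."""
    rho = np.asarray(class_densities, dtype=float)
    vol = np.asarray(class_volumes, dtype=float)
    if rho.shape != vol.shape or rho.ndim != 1:
        raise ValueError("densities and volumes must be equal-length 1D sequences")
    if np.any(rho <= 0) or np.any(vol < 0):
        raise ValueError("densities must be positive and volumes non-negative")
    vtot = vol.sum()
    if vtot <= 0:
        raise ValueError("total volume is zero")
    return float(np.dot(rho, vol) / vtot)


def total_mass(mesh, element_density) -> float:
    """Total mass in grams of a tet mesh with per-element density in g/cm^3.

    `mesh` is any object with an `element_volumes()` method returning mm^3
    (see :class:`paleofract.fe.TetMesh`).
    """
    vols = np.asarray(mesh.element_volumes(), dtype=float)  # mm^3
    rho = np.asarray(element_density, dtype=float)
    if rho.shape != vols.shape:
        raise ValueError("one density per element required")
    if np.any(vols <= 0):
        raise ValueError("mesh contains inverted or degenerate elements")
    # g/cm^3 * mm^3 = 1e-3 g
    return float(np.dot(rho, vols) * 1e-3)


@dataclass
class MaterialCard:
    """Per-class isotropic elastic properties.

    classes maps class id -> dict(rho [g/cm^3], E [MPa], nu).  Class 1 is
    cortical by convention; higher ids are cancellous classes in decreasing
    density order.
    """

    classes: dict[int, dict] = field(default_factory=dict)

    def add(self, class_id: int, rho: float, E: float, nu: float) -> None:
        if E <= 0 or rho <= 0 or not (0 <= nu < 0.5):
            raise ValueError("require E > 0, rho > 0, 0 <= nu < 0.5")
        self.classes[class_id] = {"rho": rho, "E": E, "nu": nu}

    def rho(self, class_id: int) -> float:
        return self.classes[class_id]["rho"]

    def arrays(self, element_class) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-element (rho, E, nu) arrays from per-element class ids."""
        cid = np.asarray(element_class)
        rho = np.empty(cid.shape, float)
        E = np.empty(cid.shape, float)
        nu = np.empty(cid.shape, float)
        for k, props in self.classes.items():
            m = cid == k
            rho[m], E[m], nu[m] = props["rho"], props["E"], props["nu"]
        known = np.isin(cid, list(self.classes))
        if not known.all():
            raise KeyError(f"elements reference unknown class ids {set(cid[~known])}")
        return rho, E, nu


def default_cancellous_card(densities, start_id: int = 2) -> MaterialCard:
    """Material card with cortical class 1 plus regression-mapped cancellous classes."""
    card = MaterialCard()
    card.add(1, CORTICAL["rho"], CORTICAL["E"], CORTICAL["nu"])
    for i, rho in enumerate(densities):
        card.add(start_id + i, rho, density_to_modulus(rho), NU_CANCELLOUS)
    return card


def reference_table() -> list[dict]:
    """The canonical bone-material table with a consistency check per row.

    Each cancellous row reports the tabulated modulus alongside the value the
    regression + 0.5-GPa rounding actually produces; `consistent` flags
    agreement.  The densest cancellous class (1.6 g/cm^3, tabulated 17,500 MPa)
    is known to disagree with the regression (which rounds to 18,000 MPa); the
    row is reported and flagged, not silently corrected.
    """
    tabulated = [
        ("cortical bone", 2.06, 20000.0, 0.4, False),
        ("cancellous density 1", 1.6, 17500.0, 0.3, True),
        ("cancellous density 2", 1.4, 15000.0, 0.3, True),
        ("cancellous density 3", 1.2, 12000.0, 0.3, True),
        ("cancellous density 4", 1.1, 11000.0, 0.3, True),
        ("homogenous cancellous", 1.3, 13500.0, 0.3, True),
    ]
    rows = []
    for name, rho, e_tab, nu, from_regression in tabulated:
        e_reg = density_to_modulus(rho) if from_regression else e_tab
        rows.append(
            {
                "material": name,
                "rho_g_cm3": rho,
                "E_tabulated_MPa": e_tab,
                "E_regression_MPa": e_reg,
                "nu": nu,
                "consistent": e_reg == e_tab,
            }
        )
    return rows
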