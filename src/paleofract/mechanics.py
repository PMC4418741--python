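"""Closed-form mechanics chain: fracture force, loading mass, body mass, fall kinematics.

The finite-element solution gives a *relative* answer: the applied load that best
reproduces the fracture, together with the peak von Mises strain it induces in the
fracture zone.  Because the model is linear, strain scales with force, so the force
actually required to reach the yield strain of bone follows by simple proportion.
Everything downstream of that — the equivalent loading mass, the body mass of the
animal from isometric scaling against a modern analogue, the body-weight ratio and
the minimum fall height — is ordinary Newtonian arithmetic, implemented here with
explicit rounding conventions so that printed figures can be reproduced exactly.

Units: forces in N, masses in kg, lengths in m, strains in microstrain (1e-6),
g in m/s^2 (default 9.8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "FractureForceInput",
    "BodyMassEstimate",
    "FallScenario",
    "fracture_force",
    "equivalent_mass",
    "isometric_mass",
    "body_weight_ratio",
    "fall_height",
    "impact_force_from_height",
    "round_half_up",
    "round_sig",
    "mechanics_chain",
]

G_DEFAULT = 9.8  # m/s^2
YIELD_STRAIN_DEFAULT = 6000.0  # microstrain, assumed yield strain of bone


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (5 rounds away from zero), unlike banker's rounding."""
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def round_sig(x: float, sig: int) -> float:
    """Round to `sig` significant figures, half up."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exp)


@dataclass(frozen=True)
class FractureForceInput:
    """Inputs to the strain-ratio force extrapolation.

    f_applied : load applied in the FE solution, N
    eps_peak  : peak von Mises strain in the fracture zone under that load, microstrain
    eps_yield : assumed yield strain of bone, microstrain
    """

    f_applied: float
    eps_peak: float
    eps_yield: float = YIELD_STRAIN_DEFAULT

    def __post_init__(self) -> None:
        if self.f_applied <= 0 or self.eps_peak <= 0 or self.eps_yield <= 0:
            raise ValueError("force and strains must be positive")


@dataclass(frozen=True)
class BodyMassEstimate:
    """Isometric (cube-of-length) body-mass estimate against a reference animal.

    Defaults use the Chinese giant salamander as the modern analogue:
    2 m total length, 50 kg.
    """

    l: float
    l_ref: float = 2.0
    m_ref: float = 50.0

    def __post_init__(self) -> None:
        if self.l <= 0 or self.l_ref <= 0 or self.m_ref <= 0:
            raise ValueError("lengths and masses must be positive")


def fracture_force(inp: FractureForceInput) -> float:
    """Force required for fracture: F_applied x (eps_yield / eps_peak).

    In a linear static system strain is proportional to force, so the applied
    load scales by the ratio of the yield strain to the computed peak strain.
    """
    return inp.f_applied * (inp.eps_yield / inp.eps_peak)


def equivalent_mass(force: float, g: float = G_DEFAULT) -> float:
    """Loading mass equivalent to a force: m = F / g."""
    if g <= 0:
        raise ValueError("g must be positive")
    return force / g


def isometric_mass(est: BodyMassEstimate) -> float:
    """Body mass by isometric scaling: m_ref * (l / l_ref)**3."""
    return est.m_ref * (est.l / est.l_ref) ** 3


def body_weight_ratio(force: float, body_mass: float, g: float = G_DEFAULT) -> float:
    """Force expressed in multiples of body weight: F / (m g)."""
    if force <= 0 or body_mass <= 0 or g <= 0:
        raise ValueError("inputs must be positive")
    return force / (body_mass * g)


@dataclass
class FallScenario:
    """A resolved fall: mass, impact force, deceleration distance and derived kinematics.

    s_d is the distance over which the body decelerates from free-fall to a stop
    (taken as the dorsoventral body depth); a = F/m is the deceleration;
    v_max the free-fall speed at ground contact; s_h the total fall height.
    v_i (start of free-fall) and v_f (after deceleration) are zero by contract.
    """

    m: float
    F: float
    s_d: float
    g: float = G_DEFAULT
    v_i: float = 0.0
    v_f: float = 0.0
    a: float = field(init=False)
    v_max: float = field(init=False)
    s_h: float = field(init=False)
    s_h_rounded: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.m, self.F, self.s_d, self.g) <= 0:
            raise ValueError("mass, force, distances and g must be positive")
        self.a = self.F / self.m
        self.v_max = math.sqrt(2.0 * self.a * self.s_d)
        free_fall = self.v_max**2 / (2.0 * self.g)
        self.s_h = free_fall + self.s_d
        # reported-figure mode: free-fall distance to the nearest 0.1 m first
        self.s_h_rounded = round_half_up(free_fall, 1) + self.s_d


def fall_height(
    force: float,
    m: float,
    s_d: float,
    g: float = G_DEFAULT,
) -> FallScenario:
    """Minimum fall height producing `force` on a body of mass `m`.

    Deceleration a = F/m over distance s_d gives contact speed
    v_max = sqrt(2 a s_d); the free-fall distance is v_max^2 / (2 g) and the
    total height adds the deceleration distance.  The returned scenario holds
    both the exact height (`s_h`) and the height with the free-fall distance
    rounded to 0.1 m before summing (`s_h_rounded`), which is how the worked
    figures in the literature are quoted.
    """
    return FallScenario(m=m, F=force, s_d=s_d, g=g)


def impact_force_from_height(
    s_h: float, m: float, s_d: float, g: float = G_DEFAULT
) -> float:
    """Algebraic inverse of :func:`fall_height`: F = m g (s_h - s_d) / s_d."""
    if s_h <= s_d:
        raise ValueError("fall height must exceed the deceleration distance")
    if min(m, s_d, g) <= 0:
        raise ValueError("mass, distances and g must be positive")
    return m * g * (s_h - s_d) / s_d


def scaled_deceleration_distance(s_d_ref: float, m: float, m_ref: float) -> float:
    """Rescale a deceleration distance (body depth) isometrically with mass.

    Linear dimensions scale as the cube root of mass, so
    s_d = s_d_ref * (m / m_ref)**(1/3).
    """
    if min(s_d_ref, m, m_ref) <= 0:
        raise ValueError("inputs must be positive")
    return s_d_ref * (m / m_ref) ** (1.0 / 3.0)


def mechanics_chain(
    f_applied: float = 56.1,
    eps_peak: float = 300.0,
    eps_yield: float = YIELD_STRAIN_DEFAULT,
    g: float = G_DEFAULT,
    body_lengths: tuple[float, float] = (1.0, 1.5),
    body_mass_range: tuple[float, float] = (10.0, 25.0),
    s_d: float = 0.15,
    alt_mass: float = 15.0,
) -> dict:
    """Run the full force -> mass -> fall chain and return a report dict.

    Reported values follow the conventions under which the published figures are
    quoted: the fracture force to three significant figures, the equivalent mass
    to the nearest kg, fall heights with the free-fall distance rounded to 0.1 m
    (primary mass) or the height to the nearest 10 cm (lighter animal, with the
    deceleration distance rescaled by the cube root of the mass ratio).  Exact
    values are reported alongside.
    """
    F_exact = fracture_force(
        FractureForceInput(f_applied=f_applied, eps_peak=eps_peak, eps_yield=eps_yield)
    )
    F = round_sig(F_exact, 3)
    m_eq_exact = equivalent_mass(F, g)
    m_eq = round_half_up(m_eq_exact)
    masses = [isometric_mass(BodyMassEstimate(l=l)) for l in body_lengths]
    bw = [m_eq / bm for bm in body_mass_range]
    m_hi = body_mass_range[1]
    fall_primary = fall_height(F, m_hi, s_d, g)
    s_d_alt = scaled_deceleration_distance(s_d, alt_mass, m_hi)
    fall_alt = fall_height(F, alt_mass, s_d_alt, g)
    return {
        "applied_force_N": f_applied,
        "peak_strain_ue": eps_peak,
        "yield_strain_ue": eps_yield,
        "fracture_force_exact_N": F_exact,
        "fracture_force_N": F,
        "equivalent_mass_exact_kg": m_eq_exact,
        "equivalent_mass_kg": m_eq,
        "body_mass_isometric_kg": [round_half_up(m, 1) for m in masses],
        "body_weight_ratio": [round_half_up(r) for r in sorted(bw)],
        "body_weight_ratio_exact": sorted(bw),
        "v_max_sq_m2s2": fall_primary.v_max**2,
        "v_max_ms": round_half_up(fall_primary.v_max, 2),
        "fall_height_exact_m": fall_primary.s_h,
        "fall_height_m": fall_primary.s_h_rounded,
        "fall_height_cm": round_half_up(fall_primary.s_h_rounded * 100.0),
        "alt_mass_kg": alt_mass,
        "alt_s_d_m": s_d_alt,
        "alt_fall_height_exact_m": fall_alt.s_h,
        "alt_fall_height_cm": round_half_up(fall_alt.s_h * 100.0, -1),
    }
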