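"""Forward titration simulator for multi-buffer slurry-like solutions.

The model is a closed-system ideal-solution charge balance. A mixture holds
weak acid/base systems of three kinds:

* monoprotic weak acids (the volatile-fatty-acid pool, treated as acetic
  acid),
* a diprotic acid (the carbonate system H2CO3*/HCO3-/CO32-),
* cation acids (ammonium NH4+/NH3),

each with an analytical total (mol per kg solution), reference pKa value(s)
at 25 °C and a dissociation enthalpy for van 't Hoff temperature correction.
An inert, pH-independent charge offset (net strong cations minus strong
anions) sets the initial pH. Adding strong acid (HCl) contributes Cl-,
adding strong base (NaOH) contributes Na+; the pH at any dose is the root of
the electroneutrality equation in (0, 14).

Simulated titrations emulate a dynamic-dosing titrator: dose increments are
capped (0.5 mL by default) and shrink near steep curve regions so that the
per-step pH change stays below a setpoint. Optional Gaussian pH read noise
and dose quantization provide minimal instrument realism for QC testing.

The solution mass is held fixed during dosing (titrant volume is small
against the 100 g vessel charge); activity coefficients are unity. Both
idealisations are documented limitations, not switches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CompositionError, ParameterError, ProtocolError
from .titration_io import (
    Direction,
    SlurryType,
    Storage,
    Titrant,
    TitrationRecord,
)

R_KJ = 8.314462618e-3  # gas constant, kJ mol^-1 K^-1
LN10 = math.log(10.0)
T_REF_K = 298.15  # 25 °C reference for all pKa_ref values

# molar masses for converting composition assays to molalities
M_N = 14.007  # g/mol nitrogen (TAN is reported as kg N m^-3)
M_C = 12.011  # g/mol carbon (TIC is reported as kg C m^-3)
M_ACETIC = 60.052  # g/mol acetic acid


class SpeciesKind(str, Enum):
    MONOPROTIC_ACID = "monoprotic_acid"
    DIPROTIC_ACID = "diprotic_acid"
    CATION_ACID = "cation_acid"


def pka_at_temperature(pka_ref: float, dh_kj: float, temperature_c: float) -> float:
    """Van 't Hoff shift of a pKa from 25 °C to ``temperature_c``.

    pKa(T) = pKa_ref + dH/(R ln10) * (1/T - 1/298.15 K), with dH the
    dissociation enthalpy in kJ/mol. Endothermic dissociation (dH > 0, e.g.
    ammonium) therefore has a pKa that falls as temperature rises.
    """
    t_k = temperature_c + 273.15
    return pka_ref + (dh_kj / (R_KJ * LN10)) * (1.0 / t_k - 1.0 / T_REF_K)


@dataclass(frozen=True)
class BufferSpecies:
    """One weak acid/base system: analytical total plus thermodynamics.

    ``pka_ref`` and ``dh_kj`` are scalars for monoprotic/cation acids and
    2-tuples (first, second dissociation) for diprotic acids.
    """

    name: str
    kind: SpeciesKind
    total: float  # mol per kg solution
    pka_ref: tuple[float, ...]
    dh_kj: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "kind", SpeciesKind(self.kind))
        object.__setattr__(self, "pka_ref", tuple(np.atleast_1d(self.pka_ref)))
        object.__setattr__(self, "dh_kj", tuple(np.atleast_1d(self.dh_kj)))
        if self.total < 0:
            raise ParameterError(f"{self.name}: total must be >= 0")
        n_expected = 2 if self.kind is SpeciesKind.DIPROTIC_ACID else 1
        if len(self.pka_ref) != n_expected or len(self.dh_kj) != n_expected:
            raise ParameterError(
                f"{self.name}: {self.kind.value} needs {n_expected} pKa/dH value(s)"
            )
        if n_expected == 2 and not self.pka_ref[0] < self.pka_ref[1]:
            raise ParameterError(f"{self.name}: diprotic pKa values must increase")

    def pka(self, temperature_c: float) -> tuple[float, ...]:
        return tuple(
            pka_at_temperature(p, dh, temperature_c)
            for p, dh in zip(self.pka_ref, self.dh_kj)
        )

    def charge(self, h: float, temperature_c: float) -> float:
        """Signed charge (mol/kg) carried by this system at [H+] = h."""
        if self.total == 0:
            return 0.0
        kas = [10.0 ** (-p) for p in self.pka(temperature_c)]
        if self.kind is SpeciesKind.MONOPROTIC_ACID:
            ka = kas[0]
            return -self.total * ka / (ka + h)
        if self.kind is SpeciesKind.CATION_ACID:
            ka = kas[0]
            return self.total * h / (h + ka)
        k1, k2 = kas
        denom = h * h + k1 * h + k1 * k2
        return -self.total * (k1 * h + 2.0 * k1 * k2) / denom


def acetic(total: float) -> BufferSpecies:
    """VFA pool as acetic acid: pKa 4.757 at 25 °C, dH -0.4 kJ/mol."""
    return BufferSpecies("VFA", SpeciesKind.MONOPROTIC_ACID, total, (4.757,), (-0.4,))


def carbonate(total: float) -> BufferSpecies:
    """Carbonate system: pKa1 6.35 (dH 7.6), pKa2 10.33 (dH 14.9) at 25 °C."""
    return BufferSpecies(
        "carbonate", SpeciesKind.DIPROTIC_ACID, total, (6.35, 10.33), (7.6, 14.9)
    )


def ammonium(total: float) -> BufferSpecies:
    """Ammonia buffer NH4+/NH3: pKa 9.25 at 25 °C, dH 52 kJ/mol."""
    return BufferSpecies("ammonium", SpeciesKind.CATION_ACID, total, (9.25,), (52.0,))


@dataclass(frozen=True)
class BufferMixture:
    """A buffered solution: species, temperature and inert charge offset.

    ``inert_charge_offset`` is the net non-titratable charge (strong cations
    minus strong anions, mol/kg); it fixes the zero-titrant pH. Water
    self-ionisation uses pKw_ref at 25 °C with its own van 't Hoff enthalpy.
    """

    species: tuple[BufferSpecies, ...] = ()
    temperature_c: float = 25.0
    inert_charge_offset: float = 0.0
    pkw_ref: float = 14.00
    dh_w_kj: float = 55.8

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))

    def kw(self) -> float:
        return 10.0 ** (-pka_at_temperature(self.pkw_ref, self.dh_w_kj, self.temperature_c))

    def charge_imbalance(self, h: float, added_acid: float, added_base: float) -> float:
        """Electroneutrality residual f(h); the pH is its root."""
        total = h + added_base + self.inert_charge_offset - self.kw() / h - added_acid
        for sp in self.species:
            total += sp.charge(h, self.temperature_c)
        return total

    def at_temperature(self, temperature_c: float) -> "BufferMixture":
        return replace(self, temperature_c=temperature_c)

    def diluted(self, factor: float) -> "BufferMixture":
        """Scale all totals and the inert offset by ``factor`` (mass dilution)."""
        return replace(
            self,
            species=tuple(replace(sp, total=sp.total * factor) for sp in self.species),
            inert_charge_offset=self.inert_charge_offset * factor,
        )


PH_BRACKET = (1e-4, 14.0 - 1e-4)


def solve_ph(mixture: BufferMixture, added_acid: float = 0.0, added_base: float = 0.0) -> float:
    """pH of the mixture after adding strong acid/base (mol per kg solution).

    Solves the charge balance with a bracketing root-finder; ideal activity.
    """
    lo, hi = PH_BRACKET

    def f(ph: float) -> float:
        return mixture.charge_imbalance(10.0 ** (-ph), added_acid, added_base)

    f_lo, f_hi = f(lo), f(hi)
    # f is decreasing in pH: acid side (low pH) has surplus positive charge
    if not (f_lo > 0 > f_hi):
        raise CompositionError(
            "charge balance has no root in (0, 14); check composition "
            f"(f({lo})={f_lo:.3g}, f({hi})={f_hi:.3g})"
        )
    ph = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return float(ph)


def base_dose(mixture: BufferMixture, ph: float) -> float:
    """Strong-base dose C_B(pH) (mol/kg) that brings the mixture to ``ph``.

    Closed form from the charge balance; negative values mean strong acid is
    required. This is the classical buffer-index construction: the buffer
    capacity is the pH-derivative of this dose function.
    """
    h = 10.0 ** (-ph)
    cb = mixture.kw() / h - h - mixture.inert_charge_offset
    for sp in mixture.species:
        cb -= sp.charge(h, mixture.temperature_c)
    return cb


def analytic_buffer_capacity(mixture: BufferMixture, ph: float, dph: float = 1e-4) -> float:
    """Buffer index beta = dC_B/dpH (mol kg^-1 pH^-1) by central difference.

    Independent of any fitted titration curve: it differentiates the
    closed-form dose function, so it serves as the brute-force oracle for
    the reciprocal-slope CBC pipeline.
    """
    return (base_dose(mixture, ph + dph) - base_dose(mixture, ph - dph)) / (2.0 * dph)


def neutral_offset_for_ph(mixture: BufferMixture, target_ph: float) -> float:
    """Inert charge offset that puts the zero-titrant pH at ``target_ph``."""
    h = 10.0 ** (-target_ph)
    z = mixture.kw() / h - h
    for sp in mixture.species:
        z -= sp.charge(h, mixture.temperature_c)
    return z


# ---------------------------------------------------------------------------
# protocol emulation


@dataclass(frozen=True)
class TitrationProtocol:
    """Dynamic-titration settings mirroring the laboratory protocol:
    0.5 M titrant, dose steps capped at 0.5 mL, 50 g slurry + 50 g water."""

    titrant: Titrant
    target_ph: float
    molarity: float = 0.5  # mol/L
    max_step_ml: float = 0.5
    sample_mass_kg: float = 0.05
    diluent_mass_kg: float = 0.05
    max_dph_per_step: float = 0.2
    min_step_ml: float = 1e-3
    max_steps: int = 10_000

    def __post_init__(self):
        object.__setattr__(self, "titrant", Titrant(self.titrant))
        if self.molarity <= 0 or self.max_step_ml <= 0:
            raise ParameterError("molarity and max_step_ml must be > 0")

    @property
    def solution_mass_kg(self) -> float:
        return self.sample_mass_kg + self.diluent_mass_kg


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian pH read noise and titrant dose quantization."""

    ph_sigma: float = 0.0
    dose_resolution_ml: float = 0.0


def acid_protocol(target_ph: float = 2.5, **kw) -> TitrationProtocol:
    return TitrationProtocol(titrant=Titrant.HCL, target_ph=target_ph, **kw)


def base_protocol(target_ph: float = 12.0, **kw) -> TitrationProtocol:
    return TitrationProtocol(titrant=Titrant.NAOH, target_ph=target_ph, **kw)


def simulate_titration(
    mixture: BufferMixture,
    protocol: TitrationProtocol,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    sample_id: str = "sim",
    direction: Direction | None = None,
    storage: Storage = Storage.NONE,
    week: int = 0,
    replicate: int = 1,
) -> TitrationRecord:
    """Dose titrant step by step until the target pH is crossed.

    Steps start at the protocol's cap and are halved while the resulting pH
    change exceeds ``max_dph_per_step``, down to ``min_step_ml`` (the
    steepest curve regions are traversed at the minimum step, as a real
    dynamic titrator does). With ``noise=None`` (or zero sigma) and a fixed
    mixture the output is deterministic.

    Returns a :class:`TitrationRecord` with ``slurry_type=synthetic``;
    titrant amounts are recoverable per kg slurry via
    :func:`slurrycbc.titration_io.normalize_amount`.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    is_acid = protocol.titrant is Titrant.HCL
    if direction is None:
        direction = Direction.ACIDIFY if is_acid else Direction.ALKALIZE

    mass = protocol.solution_mass_kg

    def ph_at(volume_ml: float) -> float:
        amount = volume_ml * 1e-3 * protocol.molarity / mass  # mol per kg solution
        return solve_ph(
            mixture,
            added_acid=amount if is_acid else 0.0,
            added_base=0.0 if is_acid else amount,
        )

    ph0 = ph_at(0.0)
    if (is_acid and protocol.target_ph >= ph0) or (not is_acid and protocol.target_ph <= ph0):
        raise ProtocolError(
            f"target pH {protocol.target_ph} on the wrong side of initial pH {ph0:.2f}"
        )

    volumes = [0.0]
    phs = [ph0]
    v = 0.0
    ph_prev = ph0
    for _ in range(protocol.max_steps):
        step = protocol.max_step_ml
        while True:
            trial_ph = ph_at(v + step)
            if abs(trial_ph - ph_prev) <= protocol.max_dph_per_step:
                break
            if step <= protocol.min_step_ml:
                break
            step = max(step / 2.0, protocol.min_step_ml)
        v += step
        ph_prev = trial_ph
        volumes.append(v)
        phs.append(trial_ph)
        if (is_acid and trial_ph <= protocol.target_ph) or (
            not is_acid and trial_ph >= protocol.target_ph
        ):
            break
    else:
        raise ProtocolError(
            f"target pH {protocol.target_ph} not reached within "
            f"{protocol.max_steps} dosing steps (pH stalled at {ph_prev:.2f})"
        )

    volumes_arr = np.asarray(volumes)
    phs_arr = np.asarray(phs)
    if noise.dose_resolution_ml > 0:
        volumes_arr = np.round(volumes_arr / noise.dose_resolution_ml) * noise.dose_resolution_ml
        volumes_arr = np.maximum.accumulate(volumes_arr)
    if noise.ph_sigma > 0:
        phs_arr = phs_arr + rng.normal(0.0, noise.ph_sigma, size=phs_arr.shape)
        phs_arr = np.clip(phs_arr, 1e-3, 14 - 1e-3)

    steps = pd.DataFrame(
        {
            "volume_ml": volumes_arr,
            "ph": phs_arr,
            "temperature_c": mixture.temperature_c,
        }
    )
    # collapse quantization-induced duplicate volumes, keep last reading
    steps = steps.groupby("volume_ml", as_index=False, sort=True).last()

    return TitrationRecord(
        sample_id=sample_id,
        direction=direction,
        titrant=protocol.titrant,
        titrant_molarity=protocol.molarity,
        sample_mass=protocol.sample_mass_kg,
        diluent_mass=protocol.diluent_mass_kg,
        slurry_type=SlurryType.SYNTHETIC,
        storage=storage,
        week=week,
        replicate=replicate,
        steps=steps,
    ).validate()


# ---------------------------------------------------------------------------
# composition presets

# (acetic-acid-equivalent g/kg, TAN kg N/m3, TIC kg C/m3) in fresh matter,
# assuming slurry density 1 kg/L for the volumetric assays
_COMPOSITIONS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("fattening_pig", "week0"): (9.30, 2.50, 1.48),
    ("fattening_pig", "week8_cold"): (8.10, 2.35, 1.48),
    ("fattening_pig", "week8_warm"): (4.90, 3.33, 1.99),
    ("dairy_cow", "week0"): (7.70, 2.48, 1.43),
    ("dairy_cow", "week8_cold"): (7.27, 2.31, 1.31),
    ("dairy_cow", "week8_warm"): (9.03, 2.96, 1.33),
    ("sow", "week0"): (2.90, 4.80, 1.06),
    ("sow", "week8_cold"): (3.00, 4.88, 1.45),
    ("sow", "week8_warm"): (2.93, 4.71, 1.89),
}

# fresh fattening-pig and dairy-cow slurry sit near pH 7.5; fresh sow slurry
# was distinctly alkaline (pH 8.9, high urine share)
_INITIAL_PH = {"fattening_pig": 7.5, "dairy_cow": 7.5, "sow": 8.9}


def composition_to_molal(
    acetic_eq_g_kg: float, tan_kg_n_m3: float, tic_kg_c_m3: float
) -> tuple[float, float, float]:
    """Convert assay values to mol/kg fresh slurry (density 1 kg/L)."""
    return (
        acetic_eq_g_kg / M_ACETIC,
        tan_kg_n_m3 / M_N,
        tic_kg_c_m3 / M_C,
    )


def preset_mixture(
    slurry_type: SlurryType | str,
    week_profile: str = "week0",
    temperature_c: float = 25.0,
    dilution_factor: float = 0.5,
    initial_ph: float | None = None,
) -> BufferMixture:
    """Slurry-like mixture from measured compositions of three slurry types.

    ``week_profile`` is one of ``week0``, ``week8_cold``, ``week8_warm``.
    Totals are converted to mol/kg (VFA as acetic, TAN as ammonium, TIC as
    carbonate) and scaled by ``dilution_factor`` (default 0.5 for the 1:1
    water dilution of the titration protocol). The inert charge offset is
    solved so the zero-titrant pH matches ``initial_ph`` (slurry-type
    default if omitted).
    """
    slurry_type = SlurryType(slurry_type)
    key = (slurry_type.value, week_profile)
    if key not in _COMPOSITIONS:
        raise ParameterError(
            f"no composition preset for {key}; profiles: "
            f"{sorted({k[1] for k in _COMPOSITIONS})}"
        )
    vfa, tan, tic = composition_to_molal(*_COMPOSITIONS[key])
    mixture = BufferMixture(
        species=(
            acetic(vfa * dilution_factor),
            carbonate(tic * dilution_factor),
            ammonium(tan * dilution_factor),
        ),
        temperature_c=temperature_c,
    )
    ph0 = initial_ph if initial_ph is not None else _INITIAL_PH[slurry_type.value]
    return replace(mixture, inert_charge_offset=neutral_offset_for_ph(mixture, ph0))
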