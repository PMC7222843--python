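from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import slurrycbc as s


def make_record(volumes_ml, phs, direction="acidify", temperature_c=25.0, **meta):
    """Construct a TitrationRecord from raw step arrays (test helper)."""
    titrant = "HCl" if direction == "acidify" else "NaOH"
    fields = dict(
        sample_id="test",
        direction=direction,
        titrant=titrant,
        titrant_molarity=0.5,
        sample_mass=0.05,
        diluent_mass=0.05,
    )
    fields.update(meta)
    steps = pd.DataFrame(
        {
            "volume_ml": np.asarray(volumes_ml, float),
            "ph": np.asarray(phs, float),
            "temperature_c": temperature_c,
        }
    )
    return s.TitrationRecord(steps=steps, **fields).validate()


def linear_acid_record(ph_start=7.0, ph_end=3.0, amount_end=0.2, n=60):
    """Acidification record whose pH falls linearly with titrant amount."""
    amounts = np.linspace(0.0, amount_end, n)  # mol/kg slurry
    volumes = amounts * 0.05 / 0.5 * 1000.0  # back to mL
    phs = ph_start + (ph_end - ph_start) * amounts / amount_end
    return make_record(volumes, phs)


@pytest.fixture(scope="session")
def acetate_mixture():
    mix = s.BufferMixture(species=(s.acetic(0.05),))
    return replace(mix, inert_charge_offset=s.neutral_offset_for_ph(mix, 7.5))


@pytest.fixture(scope="session")
def acetate_record(acetate_mixture):
    return s.simulate_titration(
        acetate_mixture, s.acid_protocol(2.5), sample_id="acetate"
    )


@pytest.fixture(scope="session")
def ammonium_mixture():
    mix = s.BufferMixture(species=(s.ammonium(0.05),))
    return replace(mix, inert_charge_offset=s.neutral_offset_for_ph(mix, 7.0))


@pytest.fixture(scope="session")
def ammonium_record(ammonium_mixture):
    return s.simulate_titration(
        ammonium_mixture, s.base_protocol(12.0), sample_id="ammonium"
    )


@pytest.fixture(scope="session")
def pig_mixture():
    return s.preset_mixture("fattening_pig")


@pytest.fixture(scope="session")
def pig_acid_record(pig_mixture):
    return s.simulate_titration(pig_mixture, s.acid_protocol(2.5), sample_id="pig")


@pytest.fixture(scope="session")
def pig_alk_record(pig_mixture):
    return s.simulate_titration(pig_mixture, s.base_protocol(12.0), sample_id="pig_alk")
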