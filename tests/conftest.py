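import pandas as pd
import pytest

from ecarm.bundle import EhrBundle
from ecarm.synthetic_ehr import GeneratorConfig, generate_bundle

ANCHOR = pd.Timestamp("2020-06-01")


def day(offset: int) -> pd.Timestamp:
    """Date at a day offset from the shared hand-fixture anchor."""
    return ANCHOR + pd.Timedelta(days=offset)


def make_bundle(
    patients=None, diagnoses=None, medications=None, labs=None, vitals=None,
    pro_observations=None, surgeries=None, abstraction=None,
) -> EhrBundle:
    """Hand-construct a bundle from lists of dicts; unspecified tables stay empty."""
    b = EhrBundle()
    for name, rows in (
        ("patients", patients), ("diagnoses", diagnoses), ("medications", medications),
        ("labs", labs), ("vitals", vitals), ("pro_observations", pro_observations),
        ("surgeries", surgeries), ("abstraction", abstraction),
    ):
        if rows:
            setattr(b, name, pd.DataFrame(rows))
    return b


def patient_row(pid="P1", birth=pd.Timestamp("1985-01-01"), sex="female",
                standard_weight=60.0, **extra) -> dict:
    return {"id": pid, "birth_date": birth, "sex": sex,
            "standard_weight": standard_weight, **extra}


def uste_order(pid="P1", start=ANCHOR, route="IV", dose=390.0) -> dict:
    return {"id": pid, "drug_name": "ustekinumab", "drug_class": "ustekinumab",
            "dose": dose, "route": route, "start_date": start, "end_date": start}


def med_order(pid, drug_class, start, end, dose=1.0, route="PO", name="drug") -> dict:
    return {"id": pid, "drug_name": name, "drug_class": drug_class, "dose": dose,
            "route": route, "start_date": start, "end_date": end}


@pytest.fixture(scope="session")
def small_bundle():
    """A modest synthetic bundle under default study conditions."""
    return generate_bundle(GeneratorConfig(n_patients=120, seed=42))


PERFECT_KWARGS = dict(
    visit_interval_mean=1.0,
    induction_delay_mean=0.0,
    pro_documentation_prob=1.0,
    lab_documentation_prob=1.0,
    symptom_noise_sd=0.0,
    hct_noise_sd=0.0,
    weight_noise_sd=0.0,
    abstraction_recovery_prob=1.0,
    ineligible_fraction_per_criterion={},
)


def perfect_config(n_patients=60, seed=7, **overrides) -> GeneratorConfig:
    """Noise-free, fully-documented generator: structured data equal truth."""
    kwargs = dict(PERFECT_KWARGS)
    kwargs.update(overrides)
    return GeneratorConfig(n_patients=n_patients, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def perfect_bundle():
    return generate_bundle(perfect_config())
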