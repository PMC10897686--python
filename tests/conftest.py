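from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from rx_pathways import (
    GeneratorConfig,
    StudyConfig,
    build_cohort,
    classify_cohort,
    compute_patient_metrics,
    default_code_dictionary,
    generate_archetypes,
    generate_cohort,
    read_clinical_events,
    read_demographics,
    read_prescriptions,
)


@pytest.fixture(scope="session")
def cfg() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def dictionary():
    return default_code_dictionary()


@dataclasses.dataclass
class PipelineRun:
    """Everything the pipeline produced for one synthetic cohort."""

    truth: pd.DataFrame
    prescriptions: pd.DataFrame
    clinical_events: pd.DataFrame
    cohort: pd.DataFrame
    pathway_events: pd.DataFrame
    classes: pd.DataFrame
    metrics: pd.DataFrame
    generator: GeneratorConfig


def run_synthetic(synth, cfg, dictionary, tmp_path) -> PipelineRun:
    """Write a synthetic cohort to disk and run the pipeline over the files
    (exercising the readers on every fixture)."""
    paths = synth.write(tmp_path)
    rx = read_prescriptions(paths["prescriptions"], dictionary, cfg)
    ev = read_clinical_events(paths["events"], dictionary)
    demo = read_demographics(paths["demographics"])
    assert rx.attrs["n_rejected"] == 0 and ev.attrs["n_rejected"] == 0
    cohort = build_cohort(rx, ev, demo, cfg)
    events, classes = classify_cohort(rx, ev, cohort, cfg, dictionary)
    metrics = compute_patient_metrics(rx, ev, events, cohort, cfg)
    return PipelineRun(synth.truth, rx, ev, cohort, events, classes, metrics, synth.config)


@pytest.fixture(scope="session")
def archetype_run(cfg, dictionary, tmp_path_factory) -> PipelineRun:
    synth = generate_archetypes()
    return run_synthetic(synth, cfg, dictionary, tmp_path_factory.mktemp("archetypes"))


@pytest.fixture(scope="session")
def cohort_run(cfg, dictionary, tmp_path_factory) -> PipelineRun:
    gc = GeneratorConfig(n_patients=1500, rng_seed=11)
    synth = generate_cohort(gc, cfg)
    return run_synthetic(synth, cfg, dictionary, tmp_path_factory.mktemp("cohort"))


def event_counts(pathway_events: pd.DataFrame) -> pd.DataFrame:
    """patient_id x event_type count matrix."""
    return (
        pathway_events.groupby(["patient_id", "event_type"]).size().unstack(fill_value=0)
    )
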