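import dataclasses

import numpy as np
import pytest

from csfprm import quantify
from csfprm.normalize import normalize_cascade
from csfprm.simulate import StudyDesign, default_truth, simulate_study


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign()


@pytest.fixture(scope="session")
def default_study(default_design):
    """The reference-scale study: 20/37/31 + 10 GIS over 4 batches,
    94 peptides / 41 proteins."""
    truth = default_truth(default_design, seed=11)
    return simulate_study(default_design, truth, seed=11)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(n_control=6, n_ad=8, n_nonad=6, n_gis=4, n_batches=2,
                       n_proteins=5, n_peptides=12, transitions_per_peptide=4,
                       n_reference_peptides=3, n_heavy_peptides=3,
                       n_luminex=14)


@pytest.fixture(scope="session")
def small_study(small_design):
    return simulate_study(small_design, default_truth(small_design, seed=7),
                          seed=7)


def study_matrices(study):
    """Raw peptide matrix, reference matrix and peptide->protein mapping."""
    peptides = quantify.sum_transitions(study.transitions, label="light")
    reference = quantify.sum_transitions(study.transitions, label="reference")
    light = study.transitions[study.transitions["label"] == "light"]
    mapping = light.drop_duplicates("peptide").set_index("peptide")["protein"]
    return peptides, reference, mapping


@pytest.fixture(scope="session")
def default_cascade(default_study):
    peptides, reference, mapping = study_matrices(default_study)
    stages = normalize_cascade(peptides, reference, mapping,
                               default_study.metadata)
    stages["peptides_raw"] = peptides
    return stages


def noise_free_truth(design, seed=0, keep_effects=True, bio_sd=0.0):
    """Ground truth with every noise and drift source switched off."""
    truth = default_truth(design, seed=seed)
    return dataclasses.replace(
        truth,
        noise_sd_log=0.0,
        protein_noise_sd=np.zeros(design.n_proteins),
        peptide_noise_sd=np.zeros(design.n_peptides),
        reference_noise_sd=0.0,
        transition_noise_sd_log=0.0,
        bio_sd_log=bio_sd,
        severity_sd=0.0,
        drift_offsets=np.zeros(design.n_batches),
        drift_rates=np.zeros(design.n_batches),
        effect_ad_log2=truth.effect_ad_log2 if keep_effects
        else np.zeros(design.n_proteins),
        effect_nonad_log2=truth.effect_nonad_log2 if keep_effects
        else np.zeros(design.n_proteins),
        age_beta=truth.age_beta if keep_effects
        else np.zeros(design.n_proteins),
        sex_beta=truth.sex_beta if keep_effects
        else np.zeros(design.n_proteins),
    )
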