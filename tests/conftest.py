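"""Shared fixtures: corpora, priors, table-derived profiles, record builders."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import fluoromcts as fm
from fluoromcts.prior import TokenVocabulary


@pytest.fixture(scope="session")
def toy_corpus() -> list[str]:
    return fm.load_corpus(fm.toy_corpus_path())


@pytest.fixture(scope="session")
def ngram_prior(toy_corpus):
    return fm.train_prior(toy_corpus, model="ngram", seed=0)


@pytest.fixture(scope="session")
def toy_grammar_vocab() -> TokenVocabulary:
    """Four-token grammar {C, O, =} + end used for exhaustive-oracle checks."""
    return TokenVocabulary(tokens=("^", "$", "=", "C", "O"))


@pytest.fixture(scope="session")
def toy_grammar_rewards() -> dict[str, float]:
    """Exhaustive enumeration oracle: surrogate+reward score of every valid
    SMILES over {C, O, =} up to 6 tokens, keyed by canonical SMILES."""
    params = fm.RewardParams()
    table: dict[str, float] = {}
    for k in range(1, 7):
        for combo in itertools.product("CO=", repeat=k):
            text = "".join(combo)
            try:
                mol = fm.parse_smiles(text)
            except Exception:
                continue
            table[mol.smiles_canonical] = fm.total_reward(
                fm.surrogate_evaluate(mol), params)
    return table


# (a_w, a_i, f_w, f_i) for the five reference chromophores of the published
# comparison table: the lead candidate PC, its three isomers, and the
# conventionally designed coumarin V.
REFERENCE_PROFILES = {
    "PC": (433.0, 0.192, 577.0, 0.128),
    "PC1": (430.0, 0.214, 565.0, 0.141),
    "PC2": (486.8, 0.096, 718.0, 0.063),
    "PC3": (475.0, 0.110, 702.0, 0.070),
    "V": (440.0, 0.958, 493.0, 0.990),
}


@pytest.fixture(scope="session")
def reference_profiles() -> dict[str, fm.PhotophysicalProfile]:
    return {name: fm.PhotophysicalProfile(*vals)
            for name, vals in REFERENCE_PROFILES.items()}


def make_surrogate_records(smiles: list[str]) -> list[fm.CandidateRecord]:
    """Build candidate records by evaluating given SMILES with the surrogate."""
    params = fm.RewardParams()
    records = []
    for i, s in enumerate(smiles, start=1):
        mol = fm.parse_smiles(s)
        profile = fm.surrogate_evaluate(mol)
        records.append(fm.CandidateRecord(
            molecule=mol, profile=profile,
            reward=fm.total_reward(profile, params), generation_index=i))
    return records


@pytest.fixture(scope="session")
def varied_records(toy_corpus) -> list[fm.CandidateRecord]:
    """Surrogate-evaluated records over the whole toy corpus (structural
    variety in both ring count and conjugation)."""
    return make_surrogate_records(toy_corpus)
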