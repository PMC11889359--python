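"""Shared fixtures: tiny proteomes, a synthetic worked-example scaffold, and
a small end-to-end simulated experiment.

All fixtures are generated programmatically; nothing is read from disk.
"""

import numpy as np
import pytest

from siteabpp.proteome import ProteinRecord, ProteomeIndex
from siteabpp.synthetic_data import (
    default_experiment,
    generate_proteome,
    plant_labeled_sites,
    simulate_quant_tables,
)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))


@pytest.fixture(scope="session")
def small_index() -> ProteomeIndex:
    """Three handmade proteins exercising shared and unique peptides."""
    return ProteomeIndex(
        [
            ProteinRecord("A1", "GENEA", "MKEVPVAIKTLKAGYTEWRK"),
            ProteinRecord("B1", "GENEB", "MSSEVPVAIKTLKGGSPRK"),
            ProteinRecord("C1", "GENEC", "MNPQRSTKYLWFCDEAGHIK"),
        ]
    )


def _embed(rng, length: int, inserts: dict[int, str]) -> str:
    """Random sequence of ``length`` with substrings placed at 1-based
    positions (synthetic scaffold — only the inserts are meaningful)."""
    seq = list(random_protein(rng, length))
    for start, sub in inserts.items():
        seq[start - 1 : start - 1 + len(sub)] = list(sub)
    return "".join(seq)


@pytest.fixture(scope="session")
def worked_example_index() -> ProteomeIndex:
    """Synthetic scaffold proteins carrying real probe-labeled active-site
    peptides at their canonical residue offsets.

    The scaffolds are random sequences (not the real proteins); only the
    embedded peptides and their placement are meaningful, chosen so that the
    known labeled residues (EphA2 K646, NTRK3 K572, IMPDH2 K450) fall at
    their canonical positions. Each embedded peptide is verified to occur
    exactly once.
    """
    rng = np.random.default_rng(20260928)
    # EphA2: EVPVAIKTLKAGYTE spans 640-654, so K646 is covered by both the
    # tryptic EVPVAIKTLK (mod pos 7) and the peptic IKTLKAGYTE (mod pos 2)
    epha2 = _embed(rng, 976, {640: "EVPVAIKTLKAGYTE"})
    # NTRK3: VKALKDPTL spans 571-579, K572 at mod pos 2
    ntrk3 = _embed(rng, 839, {571: "VKALKDPTL"})
    # IMPDH2: VAQGVSGAVQDKGSIHK spans 439-455, K450 at mod pos 12
    impdh2 = _embed(rng, 514, {439: "VAQGVSGAVQDKGSIHK"})
    index = ProteomeIndex(
        [
            ProteinRecord("SYN-EPHA2", "EPHA2", epha2),
            ProteinRecord("SYN-NTRK3", "NTRK3", ntrk3),
            ProteinRecord("SYN-IMPDH2", "IMPDH2", impdh2),
        ]
    )
    for pep in ("EVPVAIKTLK", "IKTLKAGYTE", "VKALKDPTL", "VAQGVSGAVQDKGSIHK"):
        assert len(index.locate(pep)) == 1, "scaffold collision; adjust seed"
    return index


@pytest.fixture(scope="session")
def small_experiment():
    """A 20-site default-noise simulated experiment (session-shared)."""
    return default_experiment(seed=11, n_sites=20)


@pytest.fixture(scope="session")
def noise_free_experiment():
    """A 20-site noise-free experiment: exact intensities, no missingness."""
    from siteabpp.synthetic_data import NoiseModel

    proteome = generate_proteome(n_proteins=30, seed=5)
    manifest = plant_labeled_sites(
        proteome, n_sites=20, competed_fraction=0.25, seed=6,
        noise=NoiseModel(cv=0.0, missing_rate=0.0, replicate_scale_sd=0.0),
    )
    return simulate_quant_tables(manifest, seed=7)
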