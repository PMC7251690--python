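"""Shared fixtures: small simulated datasets and a toy ontology."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from spaceomics import synthetic_data
from spaceomics.enrichment import load_obo
from spaceomics.proteomics_de import QuantTable
from spaceomics.rnaseq_de import CountMatrix

TOY_OBO = """format-version: 1.2

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0000001
name: branch one
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0000002
name: branch two
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0000011
name: child of one
namespace: biological_process
is_a: GO:0000001 ! branch one

[Term]
id: GO:0000012
name: child of one and two
namespace: biological_process
is_a: GO:0000001 ! branch one
is_a: GO:0000002 ! branch two

[Term]
id: GO:0000111
name: grandchild one
namespace: biological_process
is_a: GO:0000011 ! child of one

[Term]
id: GO:0000112
name: grandchild two
namespace: biological_process
is_a: GO:0000012 ! child of one and two
"""


@pytest.fixture(scope="session")
def toy_obo_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("obo") / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture(scope="session")
def toy_ontology(toy_obo_path):
    return load_obo(toy_obo_path)


@pytest.fixture(scope="session")
def small_sim():
    """A 1,500-gene simulation at the default conditions, all layers."""
    cfg = synthetic_data.SimulationConfig(
        n_genes=1500, n_proteins_per_fraction=300, frac_de=0.05, seed=7
    )
    return synthetic_data.simulate_all(cfg), cfg


@pytest.fixture()
def toy_counts():
    """2 v 2 single-gene matrix with equal library sizes."""
    counts = pd.DataFrame({"f1": [10], "f2": [12], "g1": [40], "g2": [44]}, index=["gene"])
    conditions = pd.Series({"f1": "flight", "f2": "flight", "g1": "ground", "g2": "ground"})
    libs = pd.Series(1.0, index=counts.columns)
    return CountMatrix(counts=counts, conditions=conditions, treatment="flight", library_size=libs)


def make_quant_table(rows, n_rep=3, fraction="soluble") -> QuantTable:
    """Build a QuantTable from (protein, peptide, modification, site, score,
    flight intensities, ground intensities) tuples."""
    channels = [f"ch_f{i}" for i in range(n_rep)] + [f"ch_g{i}" for i in range(n_rep)]
    data = pd.DataFrame(
        [[r[0], r[1], r[2], r[3], r[4], *r[5], *r[6]] for r in rows],
        columns=["protein_id", "peptide_seq", "modification", "site", "ion_score", *channels],
    )
    cmap = {c: ("flight" if c.startswith("ch_f") else "ground") for c in channels}
    return QuantTable(data=data, channel_map=cmap, fraction=fraction, treatment="flight")


def enumerate_hypergeom_tail(N: int, k: int, n: int, x: int) -> float:
    """Exhaustive P(X >= x): enumerate every n-subset of an N-universe with k
    successes and count overlap — the combinatorial oracle for small N."""
    universe = list(range(N))
    successes = set(range(k))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(successes.intersection(draw)) >= x:
            hits += 1
    return hits / total


def enumerate_hypergeom_point(N: int, k: int, n: int, x: int) -> float:
    universe = list(range(N))
    successes = set(range(k))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(successes.intersection(draw)) == x:
            hits += 1
    return hits / total
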