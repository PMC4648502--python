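import numpy as np
import pandas as pd
import pytest

from sigpca.core import GopcaConfig, run_gopca
from sigpca.ontology import GeneSetCollection, Ontology, OntologyTerm
from sigpca.synthetic import make_dataset


@pytest.fixture
def chain_ontology():
    """A <- B <- C is_a chain (C most specific)."""
    return Ontology({
        "A": OntologyTerm("A", "grandparent", "biological_process"),
        "B": OntologyTerm("B", "parent", "biological_process", ["A"]),
        "C": OntologyTerm("C", "child", "biological_process", ["B"]),
        "X": OntologyTerm("X", "isolated", "biological_process"),
    })


@pytest.fixture
def diamond_ontology():
    """D reaches R through two paths (D->P1->R, D->P2->R)."""
    return Ontology({
        "R": OntologyTerm("R", "root", "biological_process"),
        "P1": OntologyTerm("P1", "path one", "biological_process", ["R"]),
        "P2": OntologyTerm("P2", "path two", "biological_process", ["R"]),
        "D": OntologyTerm("D", "leaf", "biological_process", ["P1", "P2"]),
    })


@pytest.fixture
def tiny_obo(tmp_path):
    path = tmp_path / "tiny.obo"
    path.write_text("""format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: child process
namespace: biological_process
alt_id: GO:0000099
is_a: GO:0000002 ! parent process

[Term]
id: GO:0000002
name: parent process
namespace: biological_process

[Term]
id: GO:0000003
name: obsolete process
namespace: biological_process
is_obsolete: true

[Term]
id: GO:0000010
name: organelle piece
namespace: cellular_component
relationship: part_of GO:0000011 ! whole organelle

[Term]
id: GO:0000011
name: whole organelle
namespace: cellular_component

[Term]
id: GO:0000020
name: process piece
namespace: biological_process
relationship: part_of GO:0000021 ! whole process

[Term]
id: GO:0000021
name: whole process
namespace: biological_process
""")
    return path


def gaf_line(gene, go_id, evidence, qualifier=""):
    fields = [
        "UniProtKB", f"ID_{gene}", gene, qualifier, go_id, "PMID:1", evidence,
        "", "P", "", "", "protein", "taxon:9606", "20150101", "UniProt", "", "",
    ]
    return "\t".join(fields)


@pytest.fixture
def tiny_gaf(tmp_path):
    path = tmp_path / "tiny.gaf"
    lines = [
        "!gaf-version: 2.1",
        gaf_line("HBB", "GO:0000001", "IDA"),
        gaf_line("HBB", "GO:0000001", "IDA"),          # duplicate
        gaf_line("HBA1", "GO:0000001", "IEA"),         # disallowed evidence
        gaf_line("CA1", "GO:0000002", "TAS"),
        gaf_line("CA2", "GO:0000001", "IMP", "NOT"),   # negated
        gaf_line("RHAG", "GO:0000099", "IDA"),         # alt_id -> GO:0000001
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


FIXTURE_MODULES = [(40, 0.3, 3.0), (40, 0.3, 3.0), (40, 0.3, 3.0)]


def planted_dataset(seed, **kwargs):
    params = dict(
        n_genes=1000, n_samples=60, modules=FIXTURE_MODULES,
        n_decoy_sets=500, seed=seed,
    )
    params.update(kwargs)
    return make_dataset(**params)


@pytest.fixture(scope="session")
def planted():
    """Standard planted fixture: 3 disjoint 40-gene modules, effect 3 sd."""
    return planted_dataset(seed=1)


@pytest.fixture(scope="session")
def planted_result(planted):
    E, collection, ontology, truth = planted
    result = run_gopca(E, collection, ontology, GopcaConfig(seed=1))
    return result, truth


@pytest.fixture
def small_expression():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(20, 10))
    return pd.DataFrame(
        values,
        index=[f"G{i:03d}" for i in range(20)],
        columns=[f"S{j}" for j in range(10)],
    )
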