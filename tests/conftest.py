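import numpy as np
import pytest

from largeped.pedigree import Individual, Pedigree
from largeped.simulate import MarkerMap
from largeped.template import TemplateParams, generate_template


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            Individual("dad", sex=1, affection=1, genotyped=True),
            Individual("mom", sex=2, affection=1, genotyped=True),
            Individual(
                "kid", father_id="dad", mother_id="mom", sex=1, affection=2, genotyped=True
            ),
        ]
    )


@pytest.fixture
def sib_mating_pedigree() -> Pedigree:
    """Five members with a full-sib-mating loop; the child is inbred h=1/4."""
    return Pedigree(
        [
            Individual("a", sex=1),
            Individual("b", sex=2),
            Individual("s1", father_id="a", mother_id="b", sex=1),
            Individual("s2", father_id="a", mother_id="b", sex=2),
            Individual("c", father_id="s1", mother_id="s2", sex=1),
        ]
    )


@pytest.fixture
def cousin_mating_pedigree() -> Pedigree:
    """First-cousin mating: offspring has h = 1/16."""
    inds = [
        Individual("gf", sex=1),
        Individual("gm", sex=2),
        Individual("p1", father_id="gf", mother_id="gm", sex=1),
        Individual("p2", father_id="gf", mother_id="gm", sex=2),
        Individual("sp1", sex=2),
        Individual("sp2", sex=1),
        Individual("c1", father_id="p1", mother_id="sp1", sex=1),
        Individual("c2", father_id="sp2", mother_id="p2", sex=2),
        Individual("z", father_id="c1", mother_id="c2", sex=1),
    ]
    return Pedigree(inds)


@pytest.fixture(scope="session")
def default_template() -> Pedigree:
    """The full-scale study template: 13 generations, ~4,998 members,
    798 genotyped, 106 affected, consanguineous loops."""
    return generate_template(TemplateParams(seed=2024))


@pytest.fixture(scope="session")
def small_template() -> Pedigree:
    """A 30%-scale template for analyses that re-split per replicate."""
    return generate_template(TemplateParams().scaled(0.3, n_generations=10, seed=7))


@pytest.fixture(scope="session")
def default_map() -> MarkerMap:
    return MarkerMap.uniform(disease_locus=62)
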