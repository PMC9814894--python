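import numpy as np
import pytest

from cagekit import (AssemblySpec, AtomSpec, CrossLinkRule, ResidueTemplate,
                     builtin_templates, octacid4_spec)


@pytest.fixture(scope="session")
def cage_spec():
    return octacid4_spec()


@pytest.fixture(scope="session")
def cage_templates():
    return builtin_templates()


@pytest.fixture
def toy_template():
    """Minimal 3-atom chain residue A-B-C with head A and tail C."""
    return ResidueTemplate(
        name="TOY",
        atoms=[AtomSpec("A", "C", "junction"),
               AtomSpec("B", "C", "main-chain"),
               AtomSpec("C", "C", "junction")],
        bonds=[("A", "B"), ("B", "C")],
        head="A", tail="C",
        cavity_atoms=["B"],
    )


def random_toy_spec(rng: np.random.Generator, template: ResidueTemplate):
    """Random small assembly spec over the toy template, for property tests."""
    n = int(rng.integers(2, 6))
    cyclic = bool(rng.integers(0, 2))
    names = template.atom_names

    def canon(a, b, off):
        # a cyclic rule (a, b, k) installs the same undirected edges as
        # (b, a, n-k); canonicalize so duplicates are excluded up front
        if cyclic:
            return min((a, b, off % n), (b, a, (n - off) % n))
        return (a, b, off)

    forbidden = {canon(template.tail, template.head, 1)}  # sequence bonds
    rules, seen = [], set(forbidden)
    for _ in range(int(rng.integers(0, 3))):
        a, b = (str(x) for x in rng.choice(names, size=2, replace=True))
        off = int(rng.integers(1, n))
        key = canon(a, b, off)
        if key in seen:
            continue
        if cyclic and a == b and (2 * off) % n == 0:
            continue  # each edge would be installed from both ends
        seen.add(key)
        rules.append(CrossLinkRule(a, b, off))
    return AssemblySpec(sequence=[template.name] * n, cyclic=cyclic,
                        cross_links=rules)
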