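"""Packaged residue templates and assembly specs.

The HC1 building block (one quarter of the octa-anionic host) and the
four-residue cyclic assembly spec ship with the package as YAML files;
see the data files for provenance notes on the distilled connectivity.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .assembly import AssemblySpec, ResidueTemplate


def _load_yaml(filename: str) -> dict:
    ref = resources.files("cagekit").joinpath("data", filename)
    return yaml.safe_load(ref.read_text())


def hc1_template() -> ResidueTemplate:
    """The HC1 building-block template (heavy atoms only)."""
    return ResidueTemplate.from_dict(_load_yaml("hc1.yaml"))


def octacid4_spec() -> AssemblySpec:
    """Cyclic 4 x HC1 assembly spec with the three cross-link rules."""
    return AssemblySpec.from_dict(_load_yaml("octacid4.yaml"))


def builtin_templates() -> dict[str, ResidueTemplate]:
    t = hc1_template()
    return {t.name: t}
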