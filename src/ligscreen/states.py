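"""Tautomer/stereoisomer state-space enumeration for a query scaffold.

A :class:`StateSpace` describes one scaffold as a SMILES *template* with
named placeholders, a list of tautomer sites (each site contributing one
SMILES fragment per state) and a list of stereocenters (each contributing a
``@``/``@@`` tag).  Enumeration takes the full Cartesian product in a
deterministic site-major, stereo-minor order, so the number of items is
always ``prod(|site states|) * prod(|stereo configs|)``.

The shipped ``oxindole_states.yaml`` fixture encodes a 3-substituted
oxindole linked to a pyrazolone through a methylene: five pyrazolone-side
tautomers x two indole forms (lactam oxindole vs 2-hydroxy-3H-indole, which
keeps the C3 stereocenter) x two enantiomers = 20 states.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml
from rdkit import Chem

from .chemio import SmilesParseError


class StateEnumerationError(ValueError):
    """A site state produced an invalid structure, or states collide."""


@dataclass
class SiteState:
    label: str
    fragment: str


@dataclass
class TautomerSite:
    name: str
    states: List[SiteState]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError(f"site {self.name!r} has no states")


@dataclass
class StereoConfig:
    label: str
    tag: str  # "@" or "@@" (or "" for an unspecified center)


@dataclass
class Stereocenter:
    name: str
    configs: List[StereoConfig]

    def __post_init__(self) -> None:
        if not self.configs:
            raise ValueError(f"stereocenter {self.name!r} has no configs")


@dataclass
class StateSpace:
    """Declarative tautomer/stereo state space of one scaffold."""

    name: str
    template: str
    sites: List[TautomerSite] = field(default_factory=list)
    stereocenters: List[Stereocenter] = field(default_factory=list)
    #: optional map "site labels/.../stereo labels" -> display id
    aliases: Dict[str, str] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        n = 1
        for site in self.sites:
            n *= len(site.states)
        for sc in self.stereocenters:
            n *= len(sc.configs)
        return n


@dataclass
class StateItem:
    """One enumerated tautomer/stereoisomer of the scaffold."""

    item_id: str
    smiles: str
    canonical_key: str
    site_states: Tuple[str, ...]
    stereo_config: Tuple[str, ...]


def _combinations(groups: Sequence[Sequence]) -> List[Tuple]:
    """Cartesian product in row-major order (first group varies slowest)."""
    combos: List[Tuple] = [()]
    for group in groups:
        combos = [c + (g,) for c in combos for g in group]
    return combos


def enumerate_states(space: StateSpace) -> List[StateItem]:
    """Enumerate every tautomer/stereo combination of the scaffold.

    Items are ordered site-major, stereo-minor and named
    ``<space.name>_<i>`` (1-based) unless an alias covers the combination.
    All enumerated SMILES must canonicalize to distinct keys.
    """
    site_combos = _combinations([s.states for s in space.sites])
    stereo_combos = _combinations([s.configs for s in space.stereocenters])
    items: List[StateItem] = []
    seen: Dict[str, str] = {}
    i = 0
    for site_choice in site_combos:
        for stereo_choice in stereo_combos:
            i += 1
            fields = {site.name: st.fragment
                      for site, st in zip(space.sites, site_choice)}
            fields.update({sc.name: cfg.tag
                           for sc, cfg in zip(space.stereocenters, stereo_choice)})
            smiles = space.template.format(**fields)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                bad = ", ".join(f"{site.name}={st.label}"
                                for site, st in zip(space.sites, site_choice))
                raise StateEnumerationError(
                    f"state combination ({bad}) yields invalid SMILES {smiles!r}")
            key = Chem.MolToSmiles(mol)
            labels = tuple(st.label for st in site_choice)
            stereo_labels = tuple(cfg.label for cfg in stereo_choice)
            alias_key = "/".join(labels + stereo_labels)
            item_id = space.aliases.get(alias_key, f"{space.name}_{i}")
            if key in seen:
                raise StateEnumerationError(
                    f"states {seen[key]} and {item_id} canonicalize to the "
                    f"same structure {key}")
            seen[key] = item_id
            items.append(StateItem(item_id=item_id, smiles=smiles,
                                   canonical_key=key, site_states=labels,
                                   stereo_config=stereo_labels))
    assert len(items) == space.n_states
    return items


def rank_states(items: Sequence[StateItem],
                energies: Optional[Dict[str, float]] = None) -> List[StateItem]:
    """Order states by ascending energy; without energies keep input order.

    ``energies`` (e.g. relative tautomer energies in kcal/mol from an
    external quantum-chemistry run) must cover every item when given.
    """
    items = list(items)
    if energies is None:
        return items
    missing = [it.item_id for it in items if it.item_id not in energies]
    if missing:
        raise KeyError(f"energies missing for items: {missing}")
    return sorted(items, key=lambda it: (energies[it.item_id], it.item_id))


# ---------------------------------------------------------------------------
# (de)serialization


def load_state_space(path: Union[str, Path, None] = None,
                     text: Optional[str] = None) -> StateSpace:
    """Load a StateSpace from YAML (path or literal text)."""
    if text is None:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    sites = [TautomerSite(name=s["name"],
                          states=[SiteState(**st) for st in s["states"]])
             for s in raw.get("sites", [])]
    stereo = [Stereocenter(name=s["name"],
                           configs=[StereoConfig(**c) for c in s["configs"]])
              for s in raw.get("stereocenters", [])]
    return StateSpace(name=raw["name"], template=raw["template"],
                      sites=sites, stereocenters=stereo,
                      aliases=raw.get("aliases", {}))


def oxindole_state_space() -> StateSpace:
    """The shipped oxindole scaffold fixture (20 tautomer/stereo states)."""
    text = resources.files("ligscreen.data").joinpath("oxindole_states.yaml").read_text()
    return load_state_space(text=text)


def write_state_items(items: Sequence[StateItem], path: Union[str, Path]) -> Path:
    """Emit enumerated states as a .smi file (SMILES <space> id)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{it.smiles} {it.item_id}" for it in items]
    path.write_text("\n".join(lines) + "\n")
    return path
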