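"""Fragment data model and the default enumeration library.

A fragment is a tiny mono-/di-atomic (or single-ring) building block that the
stochastic enumerator attaches at an open valence site of a growing molecule.
Each fragment carries

* its heavy atoms and internal bonds,
* one *primary* attachment site (how it bonds to the growing molecule) plus
  optional secondary sites that stay open for further growth or ring fusion,
* a heteroatom-attachment flag (whether it may bond to N/O sites), and
* a dimensionless sampling weight.

The default library is the ten-fragment C/H/N/O set used throughout the
enumeration experiments: a hydrogen cap, sp3 carbon (twice, once with
double/aromatic capability), amine nitrogen, hydroxyl, ether and carbonyl
oxygens, a C-O diatomic, an acyl carbon, and benzene; an optional eleventh
olefin fragment adds non-aromatic unsaturation.  Weights are scaled by the
carbon count of the largest fragment, so single-heavy-atom fragments carry
weight 6, the olefin 3 and phenyl 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "AttachmentSite",
    "Fragment",
    "FragmentLibrary",
    "default_library",
    "scale_weight",
    "compatible_fragments",
    "VALENCE",
]

#: Standard (uncharged, organic-subset) valences.
VALENCE = {"H": 1, "C": 4, "N": 3, "O": 2}

_ORDER_VALUE = {"single": 1, "double": 2, "aromatic": 1}


class LibraryError(ValueError):
    """Raised for structurally invalid fragments or libraries."""


@dataclass(frozen=True)
class AttachmentSite:
    """One attachment point of a fragment.

    ``atom_index`` indexes into ``Fragment.atoms``; ``allowed_bond_orders``
    is a non-empty subset of {"single", "double", "aromatic"}.
    """

    atom_index: int
    allowed_bond_orders: frozenset = frozenset({"single"})

    def min_order(self) -> int:
        """Smallest bond-order value this site can attach with."""
        return min(_ORDER_VALUE[o] for o in self.allowed_bond_orders)


@dataclass(frozen=True)
class Fragment:
    label: str
    atoms: tuple  # element symbols
    internal_bonds: tuple = ()  # (i, j, order-int)
    attachment_sites: tuple = ()  # AttachmentSite; [0] is the primary site
    allow_heteroatom_attachment: str = "yes"  # "yes" | "no" | "na"
    weight: float = 6.0

    def __post_init__(self):
        if self.weight <= 0:
            raise LibraryError(f"{self.label}: weight must be positive")
        if not self.attachment_sites and self.atoms != ("H",):
            raise LibraryError(f"{self.label}: heavy fragment needs a site")
        n = len(self.atoms)
        for i, j, order in self.internal_bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise LibraryError(f"{self.label}: bad internal bond ({i},{j})")
        for site in self.attachment_sites:
            if not 0 <= site.atom_index < n:
                raise LibraryError(f"{self.label}: bad site index")
            if not site.allowed_bond_orders:
                raise LibraryError(f"{self.label}: empty bond-order set")
        # valence check: internal bonds + the heaviest attachment use
        used = [0] * n
        for i, j, order in self.internal_bonds:
            used[i] += order
            used[j] += order
        for k, site in enumerate(self.attachment_sites):
            extra = max(_ORDER_VALUE[o] for o in site.allowed_bond_orders) if k == 0 else 0
            if used[site.atom_index] + extra > VALENCE[self.atoms[site.atom_index]]:
                raise LibraryError(f"{self.label}: valence exceeded at atom "
                                   f"{site.atom_index}")

    @property
    def carbon_count(self) -> int:
        return sum(1 for a in self.atoms if a == "C")

    @property
    def is_hydrogen_cap(self) -> bool:
        return self.atoms == ("H",)

    def attach_order(self) -> int:
        """Bond order used when the enumerator attaches this fragment.

        The smallest allowed order of the primary site: fragments marked P
        attach through a sigma bond; a pure-D fragment (carbonyl oxygen)
        must use a double bond.
        """
        return self.attachment_sites[0].min_order()

    def open_valences_after_attach(self):
        """(atom_index, free_valence, accepts_double) triples left open
        after attachment.

        Only atoms named as attachment sites stay growth-active; every other
        leftover valence is hydrogen-capped.  The primary site's remaining
        valence accounts for the attachment bond itself.  ``accepts_double``
        carries the site's D marker forward: only such sites can later
        receive a double-bond attachment (e.g. the carbonyl oxygen).
        """
        if self.is_hydrogen_cap:
            return []
        used = {}
        for i, j, order in self.internal_bonds:
            used[i] = used.get(i, 0) + order
            used[j] = used.get(j, 0) + order
        out = []
        for k, site in enumerate(self.attachment_sites):
            idx = site.atom_index
            fv = VALENCE[self.atoms[idx]] - used.get(idx, 0)
            if k == 0:
                fv -= self.attach_order()
            if fv > 0:
                out.append((idx, fv, "double" in site.allowed_bond_orders))
        return out


@dataclass
class FragmentLibrary:
    fragments: list
    name: str = "custom"

    def __post_init__(self):
        labels = [f.label for f in self.fragments]
        if len(set(labels)) != len(labels):
            raise LibraryError("duplicate fragment labels")
        if not any(f.is_hydrogen_cap for f in self.fragments):
            raise LibraryError("library must contain a pure-H cap fragment")

    def __len__(self):
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def get(self, label: str) -> Fragment:
        for f in self.fragments:
            if f.label == label:
                return f
        raise KeyError(label)

    @property
    def max_carbon_count(self) -> int:
        return max(f.carbon_count for f in self.fragments)

    # ---- config-file round trip -------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "fragments": [
                {
                    "label": f.label,
                    "atoms": list(f.atoms),
                    "bonds": [list(b) for b in f.internal_bonds],
                    "sites": [
                        {"atom": s.atom_index,
                         "orders": sorted(s.allowed_bond_orders)}
                        for s in f.attachment_sites
                    ],
                    "allow_heteroatom_attachment": f.allow_heteroatom_attachment,
                    "weight": float(f.weight),
                }
                for f in self.fragments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FragmentLibrary":
        frags = []
        for fd in d["fragments"]:
            frags.append(Fragment(
                label=fd["label"],
                atoms=tuple(fd["atoms"]),
                internal_bonds=tuple(tuple(b) for b in fd.get("bonds", [])),
                attachment_sites=tuple(
                    AttachmentSite(s["atom"], frozenset(s["orders"]))
                    for s in fd.get("sites", [])
                ),
                allow_heteroatom_attachment=fd.get(
                    "allow_heteroatom_attachment", "yes"),
                weight=float(fd["weight"]),
            ))
        return cls(fragments=frags, name=d.get("name", "custom"))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FragmentLibrary":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "FragmentLibrary":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


def _site(atom, *orders):
    return AttachmentSite(atom, frozenset(orders))


def _kekule_benzene_bonds():
    # alternating Kekule ring bonds; aromaticity is re-perceived downstream
    return tuple((i, (i + 1) % 6, 1 + i % 2) for i in range(6))


def default_library(include_olefin: bool = False) -> FragmentLibrary:
    """The default ten-fragment C/H/N/O library (eleven with the olefin).

    Weights follow the carbon-count scaling rule (see :func:`scale_weight`):
    6 for every fragment with at most one carbon, 3 for the two-carbon
    olefin, 1 for six-carbon phenyl.
    """
    frags = [
        Fragment("H", ("H",), weight=6),
        Fragment("*C^P", ("C",), attachment_sites=(_site(0, "single"),),
                 weight=6),
        Fragment("*C^P,D,A", ("C",),
                 attachment_sites=(_site(0, "single", "double", "aromatic"),),
                 weight=6),
        Fragment("*N^P", ("N",), attachment_sites=(_site(0, "single"),),
                 allow_heteroatom_attachment="no", weight=6),
        # terminal hydroxyl: the oxygen attaches and is immediately H-capped
        Fragment("*O^T", ("O", "H"), internal_bonds=((0, 1, 1),),
                 attachment_sites=(_site(0, "single"),),
                 allow_heteroatom_attachment="no", weight=6),
        Fragment("*O^P", ("O",), attachment_sites=(_site(0, "single"),),
                 allow_heteroatom_attachment="no", weight=6),
        # carbonyl oxygen: double-bond attachment, closes with no open valence
        Fragment("*O^D", ("O",), attachment_sites=(_site(0, "double"),),
                 allow_heteroatom_attachment="na", weight=6),
        Fragment("^P*C-O", ("C", "O"), internal_bonds=((0, 1, 1),),
                 attachment_sites=(_site(0, "single"), _site(1, "single")),
                 allow_heteroatom_attachment="no", weight=6),
        Fragment("^A*C=O", ("C", "O"), internal_bonds=((0, 1, 2),),
                 attachment_sites=(_site(0, "single"),),
                 allow_heteroatom_attachment="yes", weight=6),
        Fragment("Phenyl (*C1,C2^D)", ("C",) * 6,
                 internal_bonds=_kekule_benzene_bonds(),
                 attachment_sites=(_site(0, "single"), _site(1, "single")),
                 weight=1),
    ]
    if include_olefin:
        frags.append(Fragment("*C=C^P", ("C", "C"),
                              internal_bonds=((0, 1, 2),),
                              attachment_sites=(_site(0, "single"),
                                                _site(1, "single")),
                              allow_heteroatom_attachment="no", weight=3))
    return FragmentLibrary(frags, name="default+olefin" if include_olefin
                           else "default")


def scale_weight(fragment: Fragment, reference_carbon_count: int) -> float:
    """Weight scaled by carbon count relative to the largest fragment.

    weight = reference_carbon_count / max(1, fragment carbon count) — for the
    default library (reference 6: phenyl) this reproduces the canonical
    weight column 6 / 3 / 1.
    """
    if reference_carbon_count < 1:
        raise LibraryError("reference_carbon_count must be >= 1")
    return reference_carbon_count / max(1, fragment.carbon_count)


def compatible_fragments(library: FragmentLibrary, site_element: str,
                         site_free_valence: int,
                         site_accepts_double: bool = True):
    """Fragments attachable at an open site, with their sampling weights.

    A fragment flagged ``no`` (or ``na``) for heteroatom attachment is
    excluded at N/O sites; a fragment whose minimum attachment bond order
    exceeds the site's free valence is excluded everywhere; a fragment that
    must attach through a double bond (the carbonyl oxygen) additionally
    requires a site whose own fragment carried the D marker
    (``site_accepts_double``).  The returned list preserves relative
    weights; it may be empty only for a library without an H cap, which the
    library invariant forbids.
    """
    if site_element not in ("C", "N", "O"):
        raise ValueError(f"unsupported site element {site_element!r}")
    if site_free_valence < 1:
        raise ValueError("site_free_valence must be >= 1")
    hetero = site_element in ("N", "O")
    out = []
    for f in library:
        if f.is_hydrogen_cap:
            out.append(f)
            continue
        if hetero and f.allow_heteroatom_attachment in ("no", "na"):
            continue
        if f.attach_order() > site_free_valence:
            continue
        if f.attach_order() == 2 and not site_accepts_double:
            continue
        out.append(f)
    return out
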