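"""Stochastic atom-level molecular enumeration.

Molecules are grown from a single carbon core whose four valences seed four
growth branches.  Each growth cycle walks the open valence sites in creation
order, draws a compatible fragment with probability proportional to its
library weight (the hydrogen cap's weight is multiplied by
``h_weight_multiplier``, the knob that damps growth and makes the branching
process subcritical), and attaches it.  After each cycle one ring closure is
attempted with probability ``ring_closure_probability``: an eligible pair of
open sites is bonded by a single bond, classified intra-chain when both
sites descend from the same core branch and inter-chain otherwise.  Growth
terminates when no open site remains (every valence is hydrogen-capped) or a
safety cap on cycles is hit, at which point all remaining sites are capped.

There is no hard molecular-weight constraint: molecules never get rejected
or truncated by size.  Termination is purely stochastic, via the hydrogen
cap.  A *constant* H weight makes total molecule size a branching-process
progeny count, which is far too over-dispersed to produce the observed
bell-shaped weight distribution of the enumerated sets; the effective H
weight therefore rises with the current heavy-atom count,

    w_H(n) = w_H,table * h_weight_multiplier * n ** growth_damping_exponent,

so small partial molecules grow almost freely while large ones are
progressively more likely to cap.  The damping exponent is a structural
constant (default 3.0, which reproduces the observed SD/mean ratio of about
0.25); ``h_weight_multiplier`` and ``ring_closure_probability`` are the two
free knobs calibrated against the target mean/SD molecular weight (see
:func:`calibrate_growth`).
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from .fragments import (FragmentLibrary, VALENCE, compatible_fragments,
                        default_library)

__all__ = [
    "EnumeratorConfig",
    "GrowingMolecule",
    "OpenSite",
    "enumerate_one",
    "enumerate_set",
    "close_ring",
    "calibrate_growth",
    "molecule_seed",
]

_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

#: Default knob values, fixed by calibrating against a target molecular
#: weight distribution of 264 +/- 65 g/mol (see docs/methods.md).
DEFAULT_H_WEIGHT_MULTIPLIER = 0.00574
DEFAULT_RING_CLOSURE_PROBABILITY = 0.30
DEFAULT_GROWTH_DAMPING_EXPONENT = 3.0


@dataclass
class OpenSite:
    """An open valence site: atom index, remaining free valence, and the
    identity of the core branch (growth chain) it descends from."""
    atom: int
    free_valence: int
    branch: int
    accepts_double: bool = False  # site's fragment carried the D marker


@dataclass
class GrowingMolecule:
    """Partial molecular graph under construction (heavy atoms only;
    hydrogens stay implicit and are realized at finalization)."""
    atoms: list = field(default_factory=list)
    bonds: list = field(default_factory=list)      # (i, j, order)
    adjacency: list = field(default_factory=list)  # list[set[int]]
    open_sites: list = field(default_factory=list)
    n_rings_closed: int = 0
    # per-atom marker: carbon already bearing a single-bonded N/O neighbor
    het_flag: list = field(default_factory=list)

    def add_atom(self, element: str) -> int:
        self.atoms.append(element)
        self.adjacency.append(set())
        self.het_flag.append(False)
        return len(self.atoms) - 1

    def add_bond(self, i: int, j: int, order: int) -> None:
        self.bonds.append((i, j, order))
        self.adjacency[i].add(j)
        self.adjacency[j].add(i)
        if order == 1:
            if self.atoms[i] == "C" and self.atoms[j] in ("N", "O"):
                self.het_flag[i] = True
            elif self.atoms[j] == "C" and self.atoms[i] in ("N", "O"):
                self.het_flag[j] = True

    @property
    def n_implicit_h(self) -> int:
        used = [0] * len(self.atoms)
        for i, j, order in self.bonds:
            used[i] += order
            used[j] += order
        return sum(VALENCE[a] - u for a, u in zip(self.atoms, used))

    @property
    def molecular_weight(self) -> float:
        """Average-atomic-mass MW including implicit hydrogens."""
        return (sum(_MASS[a] for a in self.atoms)
                + _MASS["H"] * self.n_implicit_h)

    def to_rdkit(self) -> Chem.Mol:
        em = Chem.RWMol()
        for a in self.atoms:
            em.AddAtom(Chem.Atom(a))
        for i, j, order in self.bonds:
            em.AddBond(i, j, Chem.BondType.SINGLE if order == 1
                       else Chem.BondType.DOUBLE)
        mol = em.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())


@dataclass
class EnumeratorConfig:
    library: FragmentLibrary = field(default_factory=default_library)
    allow_intra_chain: bool = True
    allow_inter_chain: bool = True
    ring_closure_probability: float = DEFAULT_RING_CLOSURE_PROBABILITY
    h_weight_multiplier: float = DEFAULT_H_WEIGHT_MULTIPLIER
    growth_damping_exponent: float = DEFAULT_GROWTH_DAMPING_EXPONENT
    max_growth_cycles: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ring_closure_probability <= 1.0:
            raise ValueError("ring_closure_probability must be in [0, 1]")
        if self.h_weight_multiplier <= 0:
            raise ValueError("h_weight_multiplier must be positive")
        if self.growth_damping_exponent < 0:
            raise ValueError("growth_damping_exponent must be >= 0")
        if self.max_growth_cycles < 1:
            raise ValueError("max_growth_cycles must be >= 1")

    def config_hash(self) -> str:
        payload = {
            "library": self.library.to_dict(),
            "allow_intra_chain": self.allow_intra_chain,
            "allow_inter_chain": self.allow_inter_chain,
            "ring_closure_probability": self.ring_closure_probability,
            "h_weight_multiplier": self.h_weight_multiplier,
            "growth_damping_exponent": self.growth_damping_exponent,
            "max_growth_cycles": self.max_growth_cycles,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class _SamplerCache:
    """Per-(element, free-valence) compatible-fragment tables with
    cumulative weights, rebuilt once per config.  The H cap is kept aside
    because its effective weight depends on the current molecule size."""

    def __init__(self, config: EnumeratorConfig):
        self.h_mult = config.h_weight_multiplier
        self.gamma = config.growth_damping_exponent
        self.tables = {}
        for element in ("C", "N", "O"):
            for fv, het_blocked, acc_d in itertools.product(
                    range(1, 5), (False, True), (False, True)):
                    frags = compatible_fragments(config.library, element, fv,
                                                 site_accepts_double=acc_d)
                    if het_blocked:
                        # geminal-heteroatom stability rule: no second
                        # single-bonded N/O on this carbon (kills gem-diol,
                        # acetal and aminal motifs); the double-bonded
                        # carbonyl oxygen stays allowed (esters, amides and
                        # acids are stable)
                        frags = [f for f in frags
                                 if f.is_hydrogen_cap
                                 or f.atoms[f.attachment_sites[0].atom_index]
                                 == "C"
                                 or f.attach_order() == 2]
                    h_frag = next(f for f in frags if f.is_hydrogen_cap)
                    others = [f for f in frags if not f.is_hydrogen_cap]
                    cum = np.cumsum([f.weight for f in others])
                    total = float(cum[-1]) if len(cum) else 0.0
                    self.tables[(element, fv, het_blocked, acc_d)] = (
                        h_frag, others, cum, total)

    def draw(self, element, fv, n_heavy, het_blocked, acc_d, rng):
        # Damping acts at carbon sites, which carry essentially all of the
        # growth; at the sparse N/O sites the H cap competes at its base
        # table weight (early capping there would only strand polar OH/NH
        # groups without limiting molecule size).
        h_frag, others, cum, total = self.tables[(element, fv, het_blocked,
                                                   acc_d)]
        w_h = h_frag.weight
        if element == "C":
            w_h *= self.h_mult * n_heavy ** self.gamma
        x = rng.random() * (w_h + total)
        if x < w_h or not others:
            return h_frag
        return others[int(np.searchsorted(cum, x - w_h, side="right"))]


def _attach(mol: GrowingMolecule, site: OpenSite, frag) -> None:
    if frag.is_hydrogen_cap:
        site.free_valence -= 1
        return
    order = frag.attach_order()
    base = len(mol.atoms)
    for a in frag.atoms:
        if a != "H":
            mol.add_atom(a)
    heavy_index = {}
    h_count = 0
    for k, a in enumerate(frag.atoms):
        if a == "H":
            h_count += 1
        else:
            heavy_index[k] = base + k - h_count
    for i, j, o in frag.internal_bonds:
        if frag.atoms[i] == "H" or frag.atoms[j] == "H":
            continue  # explicit fragment H (terminal hydroxyl) stays implicit
        mol.add_bond(heavy_index[i], heavy_index[j], o)
    primary = heavy_index[frag.attachment_sites[0].atom_index]
    mol.add_bond(site.atom, primary, order)
    site.free_valence -= order
    for idx, fv, acc_d in frag.open_valences_after_attach():
        mol.open_sites.append(OpenSite(heavy_index[idx], fv, site.branch,
                                       acc_d))


def close_ring(mol: GrowingMolecule, config: EnumeratorConfig,
               rng) -> GrowingMolecule:
    """Attempt one ring closure between two open sites.

    Eligible pairs join distinct, non-adjacent atoms (ring size >= 3) by a
    single bond, never bond two heteroatoms, and must match an active mode:
    same branch = intra-chain, different branch = inter-chain.  One pair is
    picked uniformly at random; if none is eligible the molecule is
    returned unchanged.
    """
    sites = [s for s in mol.open_sites if s.free_valence >= 1]
    if len(sites) < 2:
        return mol
    eligible = []
    for a, b in itertools.combinations(sites, 2):
        el_a, el_b = mol.atoms[a.atom], mol.atoms[b.atom]
        if a.atom == b.atom or b.atom in mol.adjacency[a.atom]:
            continue
        if el_a != "C" and el_b != "C":
            continue  # no N-N / N-O / O-O closures
        if ((el_a in ("N", "O") and mol.het_flag[b.atom])
                or (el_b in ("N", "O") and mol.het_flag[a.atom])):
            continue  # closure would put a second N/O on that carbon
        intra = a.branch == b.branch
        if intra and not config.allow_intra_chain:
            continue
        if not intra and not config.allow_inter_chain:
            continue
        eligible.append((a, b))
    if not eligible:
        return mol
    a, b = eligible[int(rng.integers(len(eligible)))]
    mol.add_bond(a.atom, b.atom, 1)
    a.free_valence -= 1
    b.free_valence -= 1
    mol.n_rings_closed += 1
    return mol


def grow(config: EnumeratorConfig, rng,
         sampler: _SamplerCache | None = None) -> GrowingMolecule:
    """Run the growth loop and return the finished molecular graph."""
    sampler = sampler or _SamplerCache(config)
    mol = GrowingMolecule()
    core = mol.add_atom("C")
    mol.open_sites = [OpenSite(core, 1, branch) for branch in range(4)]
    for _ in range(config.max_growth_cycles):
        if not mol.open_sites:
            break
        for site in list(mol.open_sites):
            if site.free_valence < 1:
                continue
            frag = sampler.draw(mol.atoms[site.atom], site.free_valence,
                                len(mol.atoms), mol.het_flag[site.atom],
                                site.accepts_double, rng)
            _attach(mol, site, frag)
        if (config.ring_closure_probability > 0
                and rng.random() < config.ring_closure_probability):
            close_ring(mol, config, rng)
        mol.open_sites = [s for s in mol.open_sites if s.free_valence >= 1]
    mol.open_sites = []  # safety cap: H-cap everything left
    return mol


def enumerate_one(config: EnumeratorConfig, rng) -> GrowingMolecule:
    """Grow a single fully capped, valence-legal, connected molecule."""
    return grow(config, rng)


def molecule_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-molecule seed substream."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


@dataclass
class EnumeratedRecord:
    index: int
    smiles: str
    mw: float
    n_rings_closed: int


def enumerate_set(config: EnumeratorConfig, n: int, master_seed=None,
                  as_smiles: bool = True):
    """Stream ``n`` enumerated molecules.

    Per-molecule RNG substreams are derived from the master seed and the
    molecule index, so any single record is reproducible in isolation.
    Yields :class:`EnumeratedRecord` (with canonical SMILES) when
    ``as_smiles`` is true, otherwise raw :class:`GrowingMolecule` graphs
    (faster; used for calibration).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = config.seed if master_seed is None else master_seed
    sampler = _SamplerCache(config)
    for i in range(n):
        rng = np.random.Generator(np.random.PCG64(molecule_seed(seed, i)))
        mol = grow(config, rng, sampler)
        if as_smiles:
            yield EnumeratedRecord(i, mol.to_smiles(), mol.molecular_weight,
                                   mol.n_rings_closed)
        else:
            yield mol


def _mw_sample(config, n, seed):
    return np.array([m.molecular_weight for m in
                     enumerate_set(config, n, master_seed=seed,
                                   as_smiles=False)])


class CalibrationError(RuntimeError):
    def __init__(self, message, best_config=None, report=None):
        super().__init__(message)
        self.best_config = best_config
        self.report = report


def calibrate_growth(config: EnumeratorConfig, target_mean_mw: float = 264.0,
                     target_sd_mw: float = 65.0, n_per_trial: int = 2000,
                     seed: int = 0, mean_tolerance: float = 10.0,
                     sd_tolerance: float = 10.0,
                     h_bounds=(0.002, 0.02), ring_bounds=(0.0, 0.8),
                     n_grid: int = 6, n_refine: int = 2):
    """Fit (h_weight_multiplier, ring_closure_probability) to a target MW
    mean/SD by iteratively refined grid search.

    Each candidate is scored on ``n_per_trial`` molecules by the relative
    squared error of sample mean and SD against the targets.  Returns
    ``(config, report)`` where the report records the search trace; raises
    :class:`CalibrationError` (carrying the best config found) when no
    candidate's validated mean lands within ``mean_tolerance``.
    """
    if target_mean_mw <= 0 or target_sd_mw <= 0:
        raise ValueError("targets must be positive")
    lo_h, hi_h = h_bounds
    lo_r, hi_r = ring_bounds
    trace = []
    best = None
    for _ in range(n_refine + 1):
        hs = np.geomspace(lo_h, hi_h, n_grid)  # response is log-scaled in h
        rs = np.unique(np.linspace(lo_r, hi_r, n_grid))
        for h in hs:
            for r in rs:
                cand = replace(config, h_weight_multiplier=float(h),
                               ring_closure_probability=float(r))
                mws = _mw_sample(cand, n_per_trial, seed)
                loss = (((mws.mean() - target_mean_mw) / mean_tolerance) ** 2
                        + ((mws.std() - target_sd_mw) / sd_tolerance) ** 2)
                trace.append({"h": float(h), "ring": float(r),
                              "mean": float(mws.mean()),
                              "sd": float(mws.std()), "loss": float(loss)})
                if best is None or loss < best["loss"]:
                    best = trace[-1]
        span_h = (hi_h - lo_h) / (n_grid - 1)
        span_r = (hi_r - lo_r) / (n_grid - 1)
        lo_h = max(h_bounds[0], best["h"] - span_h)
        hi_h = min(h_bounds[1], best["h"] + span_h)
        lo_r = max(ring_bounds[0], best["ring"] - span_r)
        hi_r = min(ring_bounds[1], best["ring"] + span_r)
    tuned = replace(config, h_weight_multiplier=best["h"],
                    ring_closure_probability=best["ring"])
    check = _mw_sample(tuned, n_per_trial, seed + 1)
    report = {"best": best, "validation_mean": float(check.mean()),
              "validation_sd": float(check.std()), "n_trials": len(trace),
              "n_per_trial": n_per_trial, "trace": trace}
    if abs(check.mean() - target_mean_mw) > mean_tolerance:
        raise CalibrationError(
            f"validated mean {check.mean():.1f} outside "
            f"{target_mean_mw} +/- {mean_tolerance}",
            best_config=tuned, report=report)
    return tuned, report
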