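"""Nearest-neighbor free energies and displacement-pathway energy landscapes.

The thermodynamic engine is the unified DNA nearest-neighbor model: a duplex
free energy is the sum of dinucleotide stack terms plus initiation penalties,
with single internal mismatches handled by the published mismatch stack
tables.  Parameters ship as a plain-text table (``data/nn_params.tsv``,
dH / dS at the 1 M NaCl reference) and are combined at the requested
temperature with an entropic per-stack salt correction
(``dS + 0.368 ln[Na+]_eq`` per stack, ``[Na+]_eq = [mono] + 3.3 sqrt([Mg2+])``).

A displacement pathway is coarse-grained into the ordered states
initial -> toehold binding (one state per base pair) -> [base breathing, for a
closed mismatched target] -> branch migration (one state per step) ->
incumbent separation, each state's free energy computed from the base pairs
present in that configuration.  The discrimination energy ddG compares the
matched and mismatched reaction free-energy changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .strand_model import ProbeSystem, reverse_complement

__all__ = [
    "ThermoParams",
    "EnergyLandscape",
    "UnsupportedDuplexError",
    "duplex_dG",
    "landscape",
    "ddG",
    "toehold_exchange_dG",
    "opening_cost",
    "association_dG",
]

GAS_CONSTANT_KCAL = 1.987204259e-3  # kcal / (mol K)

_WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class UnsupportedDuplexError(ValueError):
    """Duplex geometry outside the supported NN model (e.g. multiple mismatches)."""


def _load_tables() -> tuple[dict, dict, dict]:
    wc: dict[str, tuple[float, float]] = {}
    mm: dict[str, tuple[float, float]] = {}
    init: dict[str, tuple[float, float]] = {}
    with resources.files("mcsdr.data").joinpath("nn_params.tsv").open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("category"):
                continue
            cat, key, dh, ds, _ = line.rstrip("\n").split("\t")
            entry = (float(dh), float(ds))
            {"wc": wc, "mismatch": mm, "init": init}[cat][key] = entry
    return wc, mm, init


_WC, _MM, _INIT = _load_tables()


@dataclass(frozen=True)
class ThermoParams:
    """Conditions and table version for NN free-energy evaluation.

    Defaults are the 1 M NaCl / 37 degC reference at which the shipped table's
    dG37 column is exact.
    """

    temperature: float = 310.15  # K
    monovalent: float = 1.0  # M
    mg: float = 0.0  # M

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @classmethod
    def assay_buffer(cls, temperature: float = 310.15) -> "ThermoParams":
        """TE/Mg hybridization buffer: ~10 mM Tris counterion + 12.5 mM Mg."""
        return cls(temperature=temperature, monovalent=0.05, mg=0.0125)

    @property
    def na_equivalent(self) -> float:
        return self.monovalent + 3.3 * math.sqrt(self.mg)

    @property
    def rt(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature


def _is_wc(top: str, bot: str) -> bool:
    return (top, bot) in _WC_PAIRS


def _stack_entry(top2: str, bot2: str) -> tuple[float, float]:
    """dH/dS for one stack; ``bot2`` is the bottom dinucleotide read 3'->5'.

    Looks up the mismatch table first (it contains every parameterized stack
    involving a non-WC pair), then the WC table, in both reading directions.
    Stacks with no published parameters contribute zero.
    """
    k1 = f"{top2}/{bot2}"
    k2 = f"{bot2[::-1]}/{top2[::-1]}"
    for key in (k1, k2):
        if key in _MM:
            return _MM[key]
    for key in (k1, k2):
        if key in _WC:
            return _WC[key]
    return (0.0, 0.0)


def _init_terms(top_end: str, bot_end: str) -> tuple[float, float]:
    """Terminal initiation penalty for one duplex end."""
    if {top_end, bot_end} <= {"G", "C"}:
        return _INIT["init_G/C"]
    return _INIT["init_A/T"]


class _DuplexProfile:
    """Per-position pairing/stacking terms of a (possibly mismatched) duplex.

    ``top`` and ``bot3`` are equal-length aligned strings, bottom read 3'->5'
    so that column i is the base pair (top[i], bot3[i]).
    """

    def __init__(self, top: str, bot3: str, params: ThermoParams):
        if len(top) != len(bot3):
            raise UnsupportedDuplexError("aligned strands must have equal length")
        self.top = top
        self.bot3 = bot3
        self.params = params
        self.is_wc = [_is_wc(a, b) for a, b in zip(top, bot3)]
        salt_ds = 0.368 * math.log(params.na_equivalent)
        t = params.temperature
        self.stack_dG = []
        for i in range(len(top) - 1):
            dh, ds = _stack_entry(top[i : i + 2], bot3[i : i + 2])
            self.stack_dG.append(dh - t * (ds + salt_ds) / 1000.0)

    def sub_dG(self, runs: Sequence[tuple[int, int]]) -> float:
        """Free energy of a configuration pairing the half-open ``runs``.

        One bimolecular initiation for the molecule; terminal penalties at the
        ends of each contiguous run; stacks only within runs.
        """
        runs = [(a, b) for a, b in runs if b > a]
        if not runs:
            return 0.0
        t = self.params.temperature
        dh, ds = _INIT["init"]
        total = dh - t * ds / 1000.0
        for a, b in runs:
            for end in (a, b - 1):
                edh, eds = _init_terms(self.top[end], self.bot3[end])
                total += edh - t * eds / 1000.0
            total += sum(self.stack_dG[a : b - 1])
        return total


def _perfect_profile(seq: str, params: ThermoParams) -> _DuplexProfile:
    comp = reverse_complement(seq)[::-1]  # plain complement, aligned 3'->5'
    return _DuplexProfile(seq, comp, params)


def duplex_dG(top: str, bottom: str, params: ThermoParams | None = None) -> float:
    """NN free energy (kcal/mol) of a full-length duplex at ``params``.

    ``bottom`` is given 5'->3'; at most one internal mismatch is supported.
    """
    params = params or ThermoParams()
    if len(top) != len(bottom):
        raise UnsupportedDuplexError("strands must align full-length")
    prof = _DuplexProfile(top, bottom[::-1], params)
    n_mm = sum(not w for w in prof.is_wc)
    if n_mm > 1:
        raise UnsupportedDuplexError(f"{n_mm} mismatches; only single internal mismatches supported")
    dg = prof.sub_dG([(0, len(top))])
    if top == bottom:  # self-complementary duplex
        dh, ds = _INIT["sym"]
        dg += dh - params.temperature * ds / 1000.0
    return dg


@dataclass(frozen=True)
class EnergyLandscape:
    """Ordered pathway states with free energies relative to the initial state."""

    states: tuple[tuple[str, float], ...]
    variant: Literal["PM", "MM"]
    mode: Literal["tSDR", "mcSDR"]

    def __post_init__(self) -> None:
        if not self.states or self.states[0][0] != "initial":
            raise ValueError("landscape must start at the 'initial' state")

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.states]

    @property
    def dG(self) -> list[float]:
        return [s[1] for s in self.states]

    @property
    def initial_dG(self) -> float:
        return self.states[0][1]

    @property
    def final_dG(self) -> float:
        return self.states[-1][1]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("state_index\tlabel\tdG_kcal_mol\n")
            for i, (label, dg) in enumerate(self.states):
                fh.write(f"{i}\t{label}\t{dg:.4f}\n")


def opening_cost(system: ProbeSystem, params: ThermoParams | None = None) -> float:
    """Breathing cost (kcal/mol, positive): stack terms flanking the first
    branch-migration base pair of the matched duplex."""
    params = params or ThermoParams()
    prof = _perfect_profile(system.displacement_seq, params)
    t = system.toehold_len
    return abs(prof.stack_dG[t - 1] + prof.stack_dG[t])


def landscape(
    system: ProbeSystem,
    variant: Literal["PM", "MM"],
    mode: Literal["tSDR", "mcSDR"],
    params: ThermoParams | None = None,
) -> EnergyLandscape:
    """Coarse pathway energy landscape for one variant and probe mode.

    For a matched target (and for a mismatched target in the traditional
    probe, where the mismatch simply enters the duplex) the pathway is
    toehold binding base-by-base, branch migration step-by-step, then
    incumbent separation.  In closure mode the mismatched target nucleates on
    a toehold shortened by ``n_close`` sequestered bases, must pay a breathing
    excursion to open the closed junction, and finishes with the junction base
    unpaired (deletion-like product).
    """
    params = params or ThermoParams()
    t, b, n = system.toehold_len, system.bm_len, system.n_close
    r = system.rev_toehold_len
    core = t + b

    pm_disp = system.displacement_seq
    if variant == "PM":
        top = pm_disp
    else:
        if system.mutation is None:
            raise ValueError("MM landscape requires a mutation specification")
        top = system.target_mm.seq[:core]
    # the reporter bottom strand complements the MATCHED target
    bot3 = reverse_complement(pm_disp)[::-1]
    prof_T = _DuplexProfile(top, bot3, params)
    prof_F = _perfect_profile(system.bm_seq + system.rev_toehold_seq, params)
    f_total = prof_F.sub_dG([(0, b + r)])

    states: list[tuple[str, float]] = [("initial", 0.0)]
    closed = variant == "MM" and mode == "mcSDR"
    t_eff = t - n if closed else t

    for k in range(1, t_eff + 1):
        states.append((f"toehold_bind_{k}", prof_T.sub_dG([(0, k)])))
    toehold_dG = states[-1][1]

    if closed:
        states.append(("breathing", toehold_dG + opening_cost(system, params)))
        # Migration through the opened junction: the junction stack stays lost
        # while the three-way junction migrates, and each step exchanges one
        # incumbent stack for one invader stack (net-neutral for identical
        # sequences); the gap's full pairing deficit is charged at separation.
        level = toehold_dG + abs(prof_F.stack_dG[0])
        for j in range(1, b):
            if j > 1:
                level += prof_T.stack_dG[t + j - 1] - prof_F.stack_dG[j - 1]
            states.append((f"branch_migrate_{j}", level))
        # junction base reassigned to the spacer: product pairs skip [t_eff, t]
        final = prof_T.sub_dG([(0, t_eff), (t + 1, core)]) - f_total
    else:
        for j in range(1, b + 1):
            dg = prof_T.sub_dG([(0, t + j)]) + (prof_F.sub_dG([(j, b + r)]) - f_total)
            states.append((f"branch_migrate_{j}", dg))
        final = prof_T.sub_dG([(0, core)]) - f_total
    states.append(("incumbent_sep", final))
    return EnergyLandscape(tuple(states), variant=variant, mode=mode)


def ddG(land_pm: EnergyLandscape, land_mm: EnergyLandscape) -> float:
    """Discrimination energy (kcal/mol): mismatched minus matched reaction
    free-energy change, positive when the mismatched reaction is the less
    favorable one."""
    if not land_pm.states or not land_mm.states:
        raise ValueError("landscapes must be non-empty")
    drop_pm = land_pm.final_dG - land_pm.initial_dG
    drop_mm = land_mm.final_dG - land_mm.initial_dG
    return drop_mm - drop_pm


def toehold_exchange_dG(system: ProbeSystem, params: ThermoParams | None = None) -> float:
    """Net reaction free energy of the matched displacement (kcal/mol).

    The forward toehold's pairing gain is offset by the reverse toehold
    retained on the incumbent, so the net dG rises toward zero as
    ``rev_toehold_len`` grows."""
    return landscape(system, "PM", "mcSDR", params).final_dG


def toehold_dG(system: ProbeSystem, free_len: int, params: ThermoParams | None = None) -> float:
    """Association free energy of the first ``free_len`` toehold base pairs."""
    params = params or ThermoParams()
    if free_len < 1:
        return 0.0
    prof = _perfect_profile(system.displacement_seq, params)
    return prof.sub_dG([(0, free_len)])


def association_dG(assoc_seq: str, params: ThermoParams | None = None) -> float:
    """Helper-anchor binding energy: the association domain against its
    perfect complement."""
    return duplex_dG(assoc_seq, reverse_complement(assoc_seq), params)
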