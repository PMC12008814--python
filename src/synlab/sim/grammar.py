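"""Ground-truth regulatory grammar: motifs, affinities, syntax rules, footprints.

The grammar is the shared truth of the simulator and of the analytic oracle
predictor: per-motif amplitudes (expected reads per consensus instance), an
affinity scale beta that maps log-odds deficit to occupancy, soft
distance-dependent cooperativity rules, strictly spaced double-motif rules
with a multiplicative cooperativity fold, indirect task tracking, and the
stranded footprint kernels that turn occupancy into expected base-resolution
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from ..core import Motif, motif_from_consensus
from ..seqs import validate_acgt


class GrammarError(ValueError):
    """Raised when a grammar configuration violates its invariants."""


@dataclass(frozen=True)
class GrammarMotif:
    name: str
    consensus: str
    task: str                # the TF task reading this motif directly
    amplitude: float         # expected reads per consensus instance
    beta: Optional[float] = None  # per-motif affinity scale; None -> grammar beta

    @property
    def width(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class SoftRule:
    """Multiplicative occupancy boost on `task` from a nearby `partner` motif.

    boost factor = 1 + c * exp(-d / tau) for edge gap d <= max_range.
    Directional: only `task` occupancy is boosted.
    """

    task: str
    partner: str
    c: float
    tau: float
    max_range: float = 150.0


@dataclass(frozen=True)
class StrictRule:
    """Two half-sites at exactly `spacing` bp edge gap bind cooperatively.

    Occupancy of the whole = kappa * (occ_left + occ_right).
    """

    name: str
    half_site: str
    spacing: int
    kappa: float
    linker: str = ""


@dataclass(frozen=True)
class FootprintKernel:
    """Per-task stranded footprint pair; plus + minus sum to 1.

    For a + instance over [start, end): the plus-strand kernel is centered at
    start - 5 and the minus-strand kernel at end + 4 (last base + 5),
    emulating exonuclease stop-base pileups flanking the bound motif.
    """

    plus: np.ndarray
    minus: np.ndarray
    offset_plus: int = -5   # mode position relative to motif start
    offset_minus: int = 4   # mode position relative to motif end (half-open)

    @property
    def width(self) -> int:
        return len(self.plus)


def default_kernel(width: int = 41, sigma: float = 6.0) -> FootprintKernel:
    if width < 1 or width % 2 == 0:
        raise GrammarError("kernel width must be odd and positive")
    x = np.arange(width) - width // 2
    g = np.exp(-0.5 * (x / sigma) ** 2)
    total = 2.0 * g.sum()
    if total <= 0:
        raise GrammarError("kernel not normalizable")
    g = g / total
    return FootprintKernel(plus=g, minus=g[::-1].copy())


@dataclass
class GroundTruthGrammar:
    motifs: Dict[str, GrammarMotif]
    beta: float = 0.5
    soft_rules: List[SoftRule] = field(default_factory=list)
    strict_rules: List[StrictRule] = field(default_factory=list)
    indirect_map: Dict[str, str] = field(default_factory=dict)
    kernels: Dict[str, FootprintKernel] = field(default_factory=dict)
    depth: float = 0.01      # background reads / bp / strand for prediction
    gc: float = 0.42
    max_mismatches: int = 2  # matches beyond this are treated as background

    def __post_init__(self):
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def direct_tasks(self) -> List[str]:
        seen = []
        for m in self.motifs.values():
            if m.task not in seen:
                seen.append(m.task)
        return seen

    @property
    def task_names(self) -> List[str]:
        return self.direct_tasks + [t for t in self.indirect_map if t not in self.direct_tasks]

    def kernel_for(self, task: str) -> FootprintKernel:
        if task in self.kernels:
            return self.kernels[task]
        return self.kernels["__default__"]

    def single_motifs(self) -> List[GrammarMotif]:
        doubles = {r.name for r in self.strict_rules}
        return [m for m in self.motifs.values() if m.name not in doubles]

    def strict_rule_for(self, name: str) -> Optional[StrictRule]:
        for r in self.strict_rules:
            if r.name == name:
                return r
        return None

    def scoring_motif(self, name: str) -> Motif:
        return motif_from_consensus(name, self.motifs[name].consensus)

    def beta_for(self, name: str) -> float:
        b = self.motifs[name].beta
        return self.beta if b is None else b

    # -- validation ----------------------------------------------------
    def validate(self):
        if not self.motifs:
            raise GrammarError("grammar requires at least one motif")
        for m in self.motifs.values():
            validate_acgt(m.consensus, name=f"motif {m.name}")
            if m.amplitude < 0:
                raise GrammarError(f"motif {m.name}: amplitude must be >= 0")
            if m.beta is not None and m.beta < 0:
                raise GrammarError(f"motif {m.name}: beta must be >= 0")
        for r in self.soft_rules:
            if r.c < 0:
                raise GrammarError("soft rule boost c must be >= 0")
            if r.tau <= 0:
                raise GrammarError("soft rule tau must be > 0")
            if r.partner not in self.motifs:
                raise GrammarError(f"soft rule partner {r.partner!r} not in motifs")
        for r in self.strict_rules:
            if r.kappa < 1:
                raise GrammarError("strict rule kappa must be >= 1")
            if r.half_site not in self.motifs:
                raise GrammarError(f"strict rule half-site {r.half_site!r} not in motifs")
            if r.spacing < 0:
                raise GrammarError("strict rule spacing must be >= 0")
            if len(r.linker) != r.spacing:
                raise GrammarError("strict rule linker length must equal spacing")
        for task, driver in self.indirect_map.items():
            if driver not in self.direct_tasks:
                raise GrammarError(f"indirect task {task!r}: unknown driver {driver!r}")
        if "__default__" not in self.kernels:
            self.kernels["__default__"] = default_kernel()
        for k in self.kernels.values():
            s = k.plus.sum() + k.minus.sum()
            if (k.plus < 0).any() or (k.minus < 0).any() or not np.isclose(s, 1.0, atol=1e-8):
                raise GrammarError("footprint kernel pair must be non-negative and sum to 1")
        if self.beta < 0:
            raise GrammarError("beta must be >= 0")
        if self.depth < 0:
            raise GrammarError("depth must be >= 0")


DEFAULT_CONFIG = {
    "motifs": [
        {"name": "tead", "consensus": "ACATTCCTG", "task": "tead4", "amplitude": 20.0},
        {"name": "tfap2c", "consensus": "CCCTCAGGC", "task": "tfap2c",
         "amplitude": 50.0},
    ],
    "beta": 0.5,
    "soft_rules": [
        {"task": "tead4", "partner": "tfap2c", "c": 3.0, "tau": 40.0, "max_range": 150.0},
    ],
    "strict_rules": [
        {"name": "tead_double", "half_site": "tead", "spacing": 2, "kappa": 4.0,
         "linker": "GC"},
    ],
    "indirect_map": {"yap1": "tead4"},
    "depth": 0.01,
    "gc": 0.42,
}


def make_grammar(config: Optional[dict] = None) -> GroundTruthGrammar:
    """Build and validate a grammar from a structured config (dict).

    Unknown keys are rejected; strict-rule double motifs are materialized as
    motifs named by the rule (consensus = half + linker + half) bound by the
    half-site's task.
    """
    cfg = dict(DEFAULT_CONFIG if config is None else config)
    known = {"motifs", "beta", "soft_rules", "strict_rules", "indirect_map",
             "depth", "gc", "kernel", "max_mismatches"}
    unknown = set(cfg) - known
    if unknown:
        raise GrammarError(f"unknown grammar config keys: {sorted(unknown)}")
    motifs = {}
    for m in cfg.get("motifs", []):
        gm = GrammarMotif(name=m["name"], consensus=m["consensus"].upper(),
                          task=m["task"], amplitude=float(m["amplitude"]),
                          beta=None if m.get("beta") is None else float(m["beta"]))
        if gm.name in motifs:
            raise GrammarError(f"duplicate motif name {gm.name!r}")
        motifs[gm.name] = gm
    soft = [SoftRule(task=r["task"], partner=r["partner"], c=float(r["c"]),
                     tau=float(r["tau"]), max_range=float(r.get("max_range", 150.0)))
            for r in cfg.get("soft_rules", [])]
    strict = []
    for r in cfg.get("strict_rules", []):
        rule = StrictRule(name=r["name"], half_site=r["half_site"],
                          spacing=int(r["spacing"]), kappa=float(r["kappa"]),
                          linker=r.get("linker", "N" * int(r["spacing"])).upper())
        strict.append(rule)
    # materialize double motifs
    for rule in strict:
        if rule.half_site not in motifs:
            raise GrammarError(f"strict rule half-site {rule.half_site!r} not defined")
        half = motifs[rule.half_site]
        validate_acgt(rule.linker, name=f"strict rule {rule.name} linker")
        consensus = half.consensus + rule.linker + half.consensus
        motifs[rule.name] = GrammarMotif(name=rule.name, consensus=consensus,
                                         task=half.task,
                                         amplitude=rule.kappa * 2 * half.amplitude,
                                         beta=half.beta)
    kernels = {}
    kcfg = cfg.get("kernel", {})
    kernels["__default__"] = default_kernel(width=int(kcfg.get("width", 41)),
                                            sigma=float(kcfg.get("sigma", 6.0)))
    return GroundTruthGrammar(
        motifs=motifs,
        beta=float(cfg.get("beta", 0.5)),
        soft_rules=soft,
        strict_rules=strict,
        indirect_map=dict(cfg.get("indirect_map", {})),
        kernels=kernels,
        depth=float(cfg.get("depth", 0.01)),
        gc=float(cfg.get("gc", 0.42)),
        max_mismatches=int(cfg.get("max_mismatches", 2)),
    )
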