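"""Decay and emission data for the ²¹³Bi chain.

This module is the single source of the physical constants used by the
kinetics, transport and dosimetry layers: half-lives, branching fractions,
and per-decay emission lines (α energies, β spectrum endpoints and mean
energies, effective conversion/Auger electron bundles, effective γ lines)
for ²¹³Bi → ²¹³Po / ²⁰⁹Tl → ²⁰⁹Pb → ²⁰⁹Bi (stable sink).

α and β energies, yields and CSDA ranges in water are the published
emission data for the chain (MIRD decay schemes; ranges from NIST ESTAR
for electrons and SRIM for α-particles).  Daughter half-lives and the
Auger/conversion-electron bundles come from standard nuclear decay tables
and are user-overridable via the YAML serialization below.

Notes on specific values
------------------------
* The ²¹³Bi α branching fraction is 0.0209 (β⁻ branch 0.9791).  Published
  tabulations occasionally echo 1.94 %/decay for the α abundance; that
  figure is consistent only with the 10 μL α S-value, not with the decay
  scheme, so 2.09 % is adopted here.
* Auger + internal-conversion electrons and γ-rays are represented by
  minimal *effective* line sets (flagged ``approximate=True``): the full
  spectra are not needed because every headline dose quantity in this
  chain is α-dominated.
* α-recoil nuclei (112 keV for ²¹³Bi, 160 keV for ²¹³Po) are stored but
  excluded from S-values by default; they deposit locally when enabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

LN2 = math.log(2.0)

#: emission kinds understood by the transport engine
KINDS = ("alpha", "beta_spectrum", "electron_line", "gamma_line", "recoil")


@dataclass
class EmissionLine:
    """A single emission (or β spectrum) with per-decay yield.

    ``energy_MeV`` is the discrete energy for alpha / electron_line /
    gamma_line / recoil, and the endpoint energy E_max for beta_spectrum
    (whose mean energy is carried separately).  ``csda_range_um`` is the
    CSDA range in water, where tabulated.
    """

    kind: str
    yield_per_decay: float
    energy_MeV: float
    mean_energy_MeV: float | None = None
    csda_range_um: float | None = None
    mean_csda_range_um: float | None = None
    approximate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown emission kind {self.kind!r}")

    @property
    def effective_energy_MeV(self) -> float:
        """Mean emitted energy per emission (mean energy for spectra)."""
        if self.kind == "beta_spectrum":
            assert self.mean_energy_MeV is not None
            return self.mean_energy_MeV
        return self.energy_MeV


@dataclass
class Branch:
    """One decay branch: daughter, branch fraction and the emissions that
    accompany it (yields are per decay of the *parent*, not per branch)."""

    daughter: str
    fraction: float
    lines: list[EmissionLine] = field(default_factory=list)


@dataclass
class Nuclide:
    name: str
    half_life_s: float
    branches: list[Branch] = field(default_factory=list)

    @property
    def decay_constant_per_s(self) -> float:
        return LN2 / self.half_life_s

    def lines(self, kinds: tuple[str, ...] | None = None) -> list[EmissionLine]:
        out = []
        for br in self.branches:
            for ln in br.lines:
                if kinds is None or ln.kind in kinds:
                    out.append(ln)
        return out


SINK = "Bi-209"


@dataclass
class DecayChain:
    """Ordered ²¹³Bi chain with ²⁰⁹Bi as the stable sink."""

    nuclides: list[Nuclide]
    sink: str = SINK

    def __getitem__(self, name: str) -> Nuclide:
        for n in self.nuclides:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nuclides]

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "sink": self.sink,
            "nuclides": [asdict(n) for n in self.nuclides],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DecayChain":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        nuclides = []
        for nd in doc["nuclides"]:
            branches = [
                Branch(
                    daughter=bd["daughter"],
                    fraction=bd["fraction"],
                    lines=[EmissionLine(**ld) for ld in bd["lines"]],
                )
                for bd in nd["branches"]
            ]
            nuclides.append(
                Nuclide(name=nd["name"], half_life_s=nd["half_life_s"], branches=branches)
            )
        return cls(nuclides=nuclides, sink=doc.get("sink", SINK))


def load_chain(
    half_life_overrides: dict[str, float] | None = None,
) -> DecayChain:
    """Build the embedded ²¹³Bi decay chain.

    Parameters
    ----------
    half_life_overrides
        Optional ``{nuclide name: half-life in s}`` replacing the default
        half-lives (²¹³Bi 45.6 min, ²¹³Po 4.2 μs, ²⁰⁹Tl 2.16 min,
        ²⁰⁹Pb 3.25 h).
    """
    hl = {
        "Bi-213": 45.6 * 60.0,
        "Po-213": 4.2e-6,
        "Tl-209": 2.16 * 60.0,
        "Pb-209": 3.25 * 3600.0,
    }
    if half_life_overrides:
        hl.update(half_life_overrides)

    bi213 = Nuclide(
        name="Bi-213",
        half_life_s=hl["Bi-213"],
        branches=[
            Branch(
                daughter="Po-213",
                fraction=0.9791,
                lines=[
                    EmissionLine(
                        kind="beta_spectrum",
                        yield_per_decay=0.9791,
                        energy_MeV=1.422,
                        mean_energy_MeV=0.434,
                        csda_range_um=6650.0,
                        mean_csda_range_um=1450.0,
                    ),
                    # 440 keV transition in Po-213; yield 0.261 per decay
                    EmissionLine(
                        kind="gamma_line",
                        yield_per_decay=0.261,
                        energy_MeV=0.440,
                    ),
                    # effective conversion-electron + Auger bundle
                    EmissionLine(
                        kind="electron_line",
                        yield_per_decay=0.048,
                        energy_MeV=0.320,
                        approximate=True,
                    ),
                    EmissionLine(
                        kind="electron_line",
                        yield_per_decay=0.30,
                        energy_MeV=0.010,
                        approximate=True,
                    ),
                ],
            ),
            Branch(
                daughter="Tl-209",
                fraction=0.0209,
                lines=[
                    EmissionLine(
                        kind="alpha",
                        yield_per_decay=0.0209,
                        energy_MeV=5.87,
                        csda_range_um=46.47,
                    ),
                    EmissionLine(
                        kind="recoil",
                        yield_per_decay=0.0209,
                        energy_MeV=0.112,
                    ),
                ],
            ),
        ],
    )
    po213 = Nuclide(
        name="Po-213",
        half_life_s=hl["Po-213"],
        branches=[
            Branch(
                daughter="Pb-209",
                fraction=1.0,
                lines=[
                    EmissionLine(
                        kind="alpha",
                        yield_per_decay=1.0,
                        energy_MeV=8.38,
                        csda_range_um=81.75,
                    ),
                    EmissionLine(
                        kind="recoil",
                        yield_per_decay=1.0,
                        energy_MeV=0.160,
                    ),
                ],
            )
        ],
    )
    tl209 = Nuclide(
        name="Tl-209",
        half_life_s=hl["Tl-209"],
        branches=[
            Branch(
                daughter="Pb-209",
                fraction=1.0,
                lines=[
                    EmissionLine(
                        kind="beta_spectrum",
                        yield_per_decay=1.0,
                        energy_MeV=1.944,
                        mean_energy_MeV=0.655,
                        csda_range_um=9480.0,
                        mean_csda_range_um=2550.0,
                    ),
                    # strong γ cascade (117/465/1567 keV) folded into one
                    # effective line
                    EmissionLine(
                        kind="gamma_line",
                        yield_per_decay=1.3,
                        energy_MeV=1.10,
                        approximate=True,
                    ),
                    EmissionLine(
                        kind="electron_line",
                        yield_per_decay=0.13,
                        energy_MeV=0.120,
                        approximate=True,
                    ),
                    EmissionLine(
                        kind="electron_line",
                        yield_per_decay=0.50,
                        energy_MeV=0.012,
                        approximate=True,
                    ),
                ],
            )
        ],
    )
    pb209 = Nuclide(
        name="Pb-209",
        half_life_s=hl["Pb-209"],
        branches=[
            Branch(
                daughter=SINK,
                fraction=1.0,
                lines=[
                    EmissionLine(
                        kind="beta_spectrum",
                        yield_per_decay=1.0,
                        energy_MeV=0.644,
                        mean_energy_MeV=0.197,
                        csda_range_um=2490.0,
                        mean_csda_range_um=440.0,
                    )
                ],
            )
        ],
    )
    return DecayChain(nuclides=[bi213, po213, tl209, pb209])


def validate_chain(chain: DecayChain, raise_on_violation: bool = True) -> list[str]:
    """Check the structural invariants of a decay chain.

    Returns the list of violation messages (empty when valid); raises
    ``ValueError`` listing them unless ``raise_on_violation=False``.
    """
    violations: list[str] = []
    names = set(chain.names)
    for nuc in chain.nuclides:
        if nuc.half_life_s <= 0:
            violations.append(f"{nuc.name}: half_life_s <= 0")
        else:
            rel = abs(nuc.decay_constant_per_s * nuc.half_life_s - LN2) / LN2
            if rel > 1e-12:
                violations.append(f"{nuc.name}: λ·T½ != ln2")
        bsum = sum(br.fraction for br in nuc.branches)
        if abs(bsum - 1.0) > 1e-9:
            violations.append(f"{nuc.name}: branching sum != 1 (got {bsum:.6g})")
        for br in nuc.branches:
            if br.daughter not in names and br.daughter != chain.sink:
                violations.append(f"{nuc.name}: unknown daughter {br.daughter}")
            for ln in br.lines:
                if ln.yield_per_decay <= 0:
                    violations.append(f"{nuc.name}: yield_per_decay <= 0")
                # an effective γ line folding a cascade may carry yield > 1
                elif ln.yield_per_decay > 1.0 and not (
                    ln.approximate and ln.kind == "gamma_line"
                ):
                    violations.append(
                        f"{nuc.name}: yield_per_decay > 1 ({ln.kind} {ln.energy_MeV} MeV)"
                    )
                if ln.energy_MeV <= 0:
                    violations.append(f"{nuc.name}: energy_MeV <= 0")
                if ln.kind == "beta_spectrum":
                    if ln.mean_energy_MeV is None or not (
                        0.0 < ln.mean_energy_MeV < ln.energy_MeV
                    ):
                        violations.append(
                            f"{nuc.name}: beta_spectrum mean energy outside (0, E_max)"
                        )
    # acyclicity: walking daughters must terminate at the sink
    order = {name: i for i, name in enumerate(chain.names)}
    for nuc in chain.nuclides:
        for br in nuc.branches:
            if br.daughter in order and order[br.daughter] <= order[nuc.name]:
                violations.append(f"{nuc.name}: branch to {br.daughter} breaks chain order")
    if violations and raise_on_violation:
        raise ValueError("invalid decay chain: " + "; ".join(violations))
    return violations
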