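"""Parameterized toy strain models and designed consortia.

The generator emits minimal, hand-computable strain models: one
exchange + transport + catabolic reaction per carbon source, an optional
cofactor-boosted catabolic route, an optional auxotrophy, and a single
biomass reaction that consumes an internal precursor (plus the
auxotrophic metabolite) and emits any secretion products at fixed yields
per unit biomass.  Stoichiometries are abstract (not mass-balanced) so
every optimum stays derivable by hand; formulas can be attached where an
elemental-balance test needs them.

The designed Degrader/Helper/Potentiator consortium encodes the
cooperation structure the screening and cross-feeding modules are built
to detect:

* the degrader grows alone on glucose and secretes acetate;
* helpers are auxotrophic for that acetate (obligate cross-feeders);
* the potentiator runs on a trickle of citrate, secretes a vitamin that
  boosts everyone else's biomass yield, and receives nothing in return
  (unidirectional donor);
* the bystander consumes glucose at a strictly lower yield than the
  degrader, so an optimal community never allocates it carbon — swapping
  it in for the potentiator leaves performance unchanged (PCI = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .core import Medium, Metabolite, ModelError, Reaction, StrainModel
from .screening import build_media_series

__all__ = [
    "ToySpec",
    "chain_strain",
    "cross_feeder_pair",
    "dhp_spec",
    "make_designed_consortium",
    "make_toy_strain",
    "random_toy_community",
    "random_toy_model",
    "six_strain_spec",
]

OPEN = 1000.0
ROLES = ("degrader", "helper", "potentiator", "bystander")


@dataclass
class StrainDesign:
    """Declarative recipe consumed by :func:`make_toy_strain`."""

    strain_id: str
    role: str
    uptakes: Sequence[Tuple[str, float]]  # (metabolite, max uptake rate)
    secretions: Sequence[Tuple[str, float]] = ()  # (metabolite, yield/biomass)
    auxotrophy: Optional[Tuple[str, float]] = None  # (metabolite, demand/biomass)
    boost: Optional[Tuple[str, float, float]] = None  # (cofactor, cost, boosted yield)
    biomass_yield: float = 1.0


@dataclass
class ToySpec:
    """Consortium recipe: who is who, what they eat, secrete, and need."""

    designs: Sequence[StrainDesign]
    carbon_sources: Sequence[str]
    carbon_budget: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [d.strain_id for d in self.designs]
        if len(set(ids)) != len(ids):
            raise ModelError(f"duplicate strain ids in {ids}")
        for d in self.designs:
            if d.role not in ROLES:
                raise ModelError(f"unknown role {d.role!r} for {d.strain_id!r}")
            if d.biomass_yield <= 0:
                raise ModelError(f"{d.strain_id!r}: biomass yield must be positive")
            for _met, y in d.secretions:
                if y <= 0:
                    raise ModelError(f"{d.strain_id!r}: secretion yields must be positive")
        secreted = {m for d in self.designs for m, _ in d.secretions}
        for d in self.designs:
            if d.auxotrophy and d.auxotrophy[0] not in secreted:
                if d.auxotrophy[0] in self.carbon_sources:
                    raise ModelError(
                        f"{d.strain_id!r}: auxotrophy metabolite "
                        f"{d.auxotrophy[0]!r} must be partner-secreted or absent "
                        "from every medium"
                    )

    @property
    def roles(self) -> Dict[str, str]:
        return {d.strain_id: d.role for d in self.designs}


def _met(met_id: str, compartment: str, formulas: Mapping[str, str]) -> Metabolite:
    return Metabolite(
        id=met_id, compartment=compartment, formula=formulas.get(met_id.rsplit("_", 1)[0])
    )


def make_toy_strain(
    strain_id: str,
    uptakes: Sequence[Union[str, Tuple[str, float]]],
    secretions: Sequence[Tuple[str, float]] = (),
    auxotrophy: Optional[Tuple[str, float]] = None,
    boost: Optional[Tuple[str, float, float]] = None,
    biomass_yield: float = 1.0,
    formulas: Optional[Mapping[str, str]] = None,
) -> StrainModel:
    """Minimal strain model around one internal precursor.

    Per uptake ``u`` (capped at its stated rate): ``EX_u``, inbound
    transport, and a catabolic route ``u_c -> yield * prec_c``.  With a
    ``boost = (cofactor, cost, boosted_yield)``, a second route
    ``u_c + cost * cof_c -> boosted_yield * prec_c`` plus cofactor uptake
    machinery.  The biomass reaction consumes one ``prec_c`` (plus the
    auxotrophic metabolite, if any) and emits each secretion product at
    its yield.  Always at most 12 reactions and valid under QC.
    """
    if biomass_yield <= 0:
        raise ModelError("biomass yield must be positive")
    formulas = formulas or {}
    norm_uptakes: List[Tuple[str, float]] = [
        (u, OPEN) if isinstance(u, str) else (u[0], float(u[1])) for u in uptakes
    ]
    if not norm_uptakes:
        raise ModelError(f"{strain_id!r}: at least one uptake is required")
    uptake_ids = [u for u, _ in norm_uptakes]
    secretion_ids = [s for s, _ in secretions]
    overlap = set(uptake_ids) & set(secretion_ids)
    if overlap or len(set(uptake_ids)) != len(uptake_ids):
        raise ModelError(
            f"{strain_id!r}: duplicate metabolite roles {sorted(overlap) or uptake_ids}"
        )

    mets: Dict[str, Metabolite] = {}
    rxns: List[Reaction] = []

    def ensure(met_id: str, compartment: str) -> str:
        full = f"{met_id}_{compartment}"
        mets.setdefault(full, _met(full, compartment, formulas))
        return full

    prec = ensure("prec", "c")

    def add_uptake_machinery(met_id: str, cap: float) -> str:
        e = ensure(met_id, "e")
        c = ensure(met_id, "c")
        rxns.append(Reaction(f"EX_{met_id}", {e: -1.0}, -cap, OPEN, is_exchange=True))
        rxns.append(Reaction(f"T_{met_id}", {e: -1.0, c: 1.0}, 0.0, OPEN))
        return c

    for met_id, cap in norm_uptakes:
        c = add_uptake_machinery(met_id, cap)
        rxns.append(
            Reaction(f"CAT_{met_id}", {c: -1.0, prec: biomass_yield}, 0.0, OPEN)
        )

    if boost is not None:
        cof, cost, boosted = boost
        if cof in uptake_ids or cof in secretion_ids:
            raise ModelError(f"{strain_id!r}: duplicate metabolite roles [{cof!r}]")
        if cost <= 0 or boosted <= biomass_yield:
            raise ModelError(
                f"{strain_id!r}: boost must cost > 0 and beat the basal yield"
            )
        cof_c = add_uptake_machinery(cof, OPEN)
        for met_id, _cap in norm_uptakes:
            c = f"{met_id}_c"
            rxns.append(
                Reaction(
                    f"CATB_{met_id}", {c: -1.0, cof_c: -cost, prec: boosted}, 0.0, OPEN
                )
            )

    bio_stoich: Dict[str, float] = {prec: -1.0}
    if auxotrophy is not None:
        aux, demand = auxotrophy
        if demand <= 0:
            raise ModelError(f"{strain_id!r}: auxotrophic demand must be positive")
        if aux in uptake_ids or aux in secretion_ids:
            raise ModelError(f"{strain_id!r}: duplicate metabolite roles [{aux!r}]")
        aux_c = add_uptake_machinery(aux, OPEN)
        bio_stoich[aux_c] = -demand
    for met_id, yield_ in secretions:
        e = ensure(met_id, "e")
        c = ensure(met_id, "c")
        rxns.append(Reaction(f"T_{met_id}", {c: -1.0, e: 1.0}, 0.0, OPEN))
        rxns.append(Reaction(f"EX_{met_id}", {e: -1.0}, 0.0, OPEN, is_exchange=True))
        bio_stoich[c] = yield_
    rxns.append(Reaction("BIOMASS", bio_stoich, 0.0, OPEN, is_biomass=True))

    if len(rxns) > 12:
        raise ModelError(
            f"{strain_id!r}: design expands to {len(rxns)} reactions (> 12)"
        )
    return StrainModel(strain_id, mets.values(), rxns)


def build_design(design: StrainDesign, formulas: Optional[Mapping[str, str]] = None) -> StrainModel:
    return make_toy_strain(
        design.strain_id,
        design.uptakes,
        design.secretions,
        design.auxotrophy,
        design.boost,
        design.biomass_yield,
        formulas,
    )


# ---------------------------------------------------------------------------
# Designed consortia
# ---------------------------------------------------------------------------

def dhp_spec(seed: int = 0) -> ToySpec:
    """Three-member Degrader/Helper/Potentiator consortium.

    On glucose alone (C=1) only the degrader can enter carbon, so
    removing it zeroes the community.  From C=2 the potentiator's citrate
    trickle funds vitamin secretion that raises the degrader's and
    helper's yields — the PCI > 0 case."""
    return ToySpec(
        designs=[
            StrainDesign(
                "d1", "degrader",
                uptakes=[("glc", OPEN)],
                secretions=[("ace", 0.5)],
                boost=("vit", 0.05, 1.5),
                biomass_yield=1.0,
            ),
            StrainDesign(
                "h1", "helper",
                uptakes=[("ace", OPEN)],
                boost=("vit", 0.05, 0.75),
                biomass_yield=0.5,
            ),
            StrainDesign(
                "p1", "potentiator",
                uptakes=[("cit", 1.0)],
                secretions=[("vit", 2.0)],
                biomass_yield=1.0,
            ),
        ],
        carbon_sources=["glc", "cit"],
        seed=seed,
    )


def six_strain_spec(seed: int = 0) -> ToySpec:
    """Six-member pool for the full combination screen: two degraders,
    two helpers (one doubly auxotrophic), a potentiator, a bystander."""
    base = dhp_spec(seed)
    designs = list(base.designs) + [
        StrainDesign(
            "d2", "degrader",
            uptakes=[("cit", OPEN), ("fum", OPEN)],
            secretions=[("ace", 0.25)],
            biomass_yield=0.8,
        ),
        StrainDesign(
            "h2", "helper",
            uptakes=[("ace", OPEN)],
            auxotrophy=("vit", 0.02),
            biomass_yield=0.6,
        ),
        StrainDesign(
            "y1", "bystander",
            uptakes=[("glc", OPEN)],
            biomass_yield=0.5,
        ),
    ]
    return ToySpec(
        designs=designs,
        carbon_sources=["glc", "cit", "ace", "fum"],
        seed=seed,
    )


def make_designed_consortium(
    spec: ToySpec,
) -> Tuple[Dict[str, StrainModel], List[Medium]]:
    """Models plus the C = 1, 2, ... media series for a consortium spec.

    Deterministic for a given spec (the seed is recorded provenance; the
    designed stoichiometries are fixed so optima stay hand-computable).
    """
    models = {d.strain_id: build_design(d) for d in spec.designs}
    media = build_media_series(list(spec.carbon_sources), spec.carbon_budget)
    return models, media


# ---------------------------------------------------------------------------
# Hand fixtures
# ---------------------------------------------------------------------------

def chain_strain(strain_id: str = "t1", uptake_cap: float = OPEN) -> StrainModel:
    """Linear glucose -> biomass chain: EX_glc, transport, biomass (1:1)."""
    mets = [Metabolite("glc_e", "e"), Metabolite("glc_c", "c")]
    rxns = [
        Reaction("EX_glc", {"glc_e": -1.0}, -uptake_cap, OPEN, is_exchange=True),
        Reaction("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, OPEN),
        Reaction("BIOMASS", {"glc_c": -1.0}, 0.0, OPEN, is_biomass=True),
    ]
    return StrainModel(strain_id, mets, rxns)


def cross_feeder_pair() -> Tuple[StrainModel, StrainModel]:
    """The worked obligate pair.

    A: glc -> biomass_A + X (1:1:1) plus a growth-free route glc -> X;
    B: 2 X -> biomass_B.  On 10 glucose: no_limitation gives total 15
    (A=10, B=5); equal coupling gives mu=5 each; targeting B gives 5.
    """
    a = StrainModel(
        "A",
        [
            Metabolite("glc_e", "e"), Metabolite("glc_c", "c"),
            Metabolite("x_c", "c"), Metabolite("x_e", "e"),
        ],
        [
            Reaction("EX_glc", {"glc_e": -1.0}, -OPEN, OPEN, is_exchange=True),
            Reaction("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, OPEN),
            Reaction("BIOMASS", {"glc_c": -1.0, "x_c": 1.0}, 0.0, OPEN, is_biomass=True),
            Reaction("SPILL", {"glc_c": -1.0, "x_c": 1.0}, 0.0, OPEN),
            Reaction("T_x", {"x_c": -1.0, "x_e": 1.0}, 0.0, OPEN),
            Reaction("EX_x", {"x_e": -1.0}, 0.0, OPEN, is_exchange=True),
        ],
    )
    b = StrainModel(
        "B",
        [Metabolite("x_e", "e"), Metabolite("x_c", "c")],
        [
            Reaction("EX_x", {"x_e": -1.0}, -OPEN, OPEN, is_exchange=True),
            Reaction("T_x", {"x_e": -1.0, "x_c": 1.0}, 0.0, OPEN),
            Reaction("BIOMASS", {"x_c": -2.0}, 0.0, OPEN, is_biomass=True),
        ],
    )
    return a, b


# ---------------------------------------------------------------------------
# Random generation for property and oracle tests
# ---------------------------------------------------------------------------

_CARBONS = ("glc", "cit", "ace", "fum")
_INTERMEDIATES = ("m1", "m2")


def random_toy_model(seed: int) -> StrainModel:
    """Seeded random single strain, <= 8 reactions (oracle-sized)."""
    rng = np.random.default_rng(seed)
    carbon = str(rng.choice(_CARBONS))
    cap = float(np.round(rng.uniform(1.0, 20.0), 3))
    yield_ = float(np.round(rng.uniform(0.2, 1.5), 3))
    secretions: List[Tuple[str, float]] = []
    if rng.random() < 0.5:
        secretions.append((str(rng.choice(_INTERMEDIATES)), float(np.round(rng.uniform(0.1, 1.0), 3))))
    return make_toy_strain(
        f"r{seed}", [(carbon, cap)], secretions, biomass_yield=yield_
    )


def random_oracle_community(
    seed: int,
) -> Tuple[Dict[str, StrainModel], Medium]:
    """Seeded two-strain community small enough for the brute-force
    vertex-enumeration oracle (about a dozen fluxes): one carbon user
    that may secrete an intermediate, plus one strain eating either a
    second carbon or that intermediate."""
    rng = np.random.default_rng(seed)
    carbons = list(rng.choice(_CARBONS, size=2, replace=False))
    y1, y2 = (float(np.round(rng.uniform(0.2, 1.5), 3)) for _ in range(2))
    cap1, cap2 = (float(np.round(rng.uniform(1.0, 15.0), 3)) for _ in range(2))
    cross_feed = bool(rng.random() < 0.5)
    secretions = [("m1", float(np.round(rng.uniform(0.2, 1.0), 3)))] if cross_feed else []
    s1 = make_toy_strain("s1", [(str(carbons[0]), cap1)], secretions, biomass_yield=y1)
    second_source = "m1" if cross_feed else str(carbons[1])
    s2 = make_toy_strain("s2", [(second_source, cap2)], biomass_yield=y2)
    amounts = {str(carbons[0]): float(np.round(rng.uniform(5.0, 30.0), 3))}
    if not cross_feed:
        amounts[str(carbons[1])] = float(np.round(rng.uniform(5.0, 30.0), 3))
    medium = Medium(name=f"oracle{seed}", amounts=amounts)
    return {"s1": s1, "s2": s2}, medium


def random_toy_community(
    seed: int, n_strains: Optional[int] = None
) -> Tuple[Dict[str, StrainModel], Medium]:
    """Seeded random consortium (2-6 strains, <= 12 reactions each) with a
    random carbon medium; bit-reproducible for a given seed."""
    rng = np.random.default_rng(seed)
    n = int(n_strains if n_strains is not None else rng.integers(2, 7))
    models: Dict[str, StrainModel] = {}
    secreted: List[str] = []
    for i in range(n):
        sid = f"s{i + 1}"
        n_uptakes = int(rng.integers(1, 3))
        sources = list(rng.choice(_CARBONS, size=n_uptakes, replace=False))
        uptakes = [
            (str(s), float(np.round(rng.uniform(1.0, 20.0), 3))) for s in sources
        ]
        secretions: List[Tuple[str, float]] = []
        if rng.random() < 0.6:
            met = str(rng.choice(_INTERMEDIATES))
            secretions.append((met, float(np.round(rng.uniform(0.1, 1.0), 3))))
        auxotrophy = None
        if secreted and rng.random() < 0.3:
            candidates = [m for m in secreted if m not in {s for s, _ in secretions}]
            if candidates:
                auxotrophy = (
                    str(rng.choice(candidates)),
                    float(np.round(rng.uniform(0.01, 0.2), 3)),
                )
        models[sid] = make_toy_strain(
            sid,
            uptakes,
            secretions,
            auxotrophy=auxotrophy,
            biomass_yield=float(np.round(rng.uniform(0.2, 1.5), 3)),
        )
        secreted.extend(m for m, _ in secretions)
    amounts = {
        c: float(np.round(rng.uniform(5.0, 50.0), 3))
        for c in _CARBONS
        if rng.random() < 0.8
    }
    amounts.setdefault(str(rng.choice(_CARBONS)), float(np.round(rng.uniform(5.0, 50.0), 3)))
    medium = Medium(name=f"rand{seed}", amounts=amounts)
    return models, medium
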