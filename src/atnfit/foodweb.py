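"""Food-web structure and deterministic bioenergetic (ATN) dynamics.

A :class:`FoodWeb` is a directed consumer–resource network over guilds
(functional groups modelled as single biomass pools) plus exactly one
detritus pool.  Biomass dynamics follow an allometric-trophic-network
style ODE system: the producer grows logistically against a system-wide
carrying capacity ``K`` and loses biomass to grazing and exudation;
consumers gain assimilated intake through saturating functional
responses, pay maintenance metabolism, lose biomass to predation and to
catches; detritus collects egested (unassimilated) intake and producer
exudation and is depleted by detritivory.

All rates are per year, all biomasses in tonnes/km^2.  The drift is
evaluated in vectorized form so that likelihoods over many years cost a
single array pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Guild",
    "FoodWeb",
    "RateParameters",
    "Trajectory",
    "logistic_growth",
    "functional_response",
    "drift",
    "euler_step",
    "simulate_deterministic",
    "count_parameters",
]

ROLES = ("producer", "consumer", "detritus")


@dataclass(frozen=True)
class Guild:
    """One node of the food web.

    Parameters
    ----------
    name
        Unique label, e.g. ``"perch"``.
    role
        ``"producer"``, ``"consumer"`` or ``"detritus"``.
    max_body_mass
        Maximum published body mass in grams; used only to derive
        allometric lower bounds for metabolic rates of fish guilds.
    has_catch
        Whether annual catch data exist for this guild.
    """

    name: str
    role: str
    max_body_mass: float | None = None
    has_catch: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for guild {self.name!r}")
        if self.max_body_mass is not None and not self.max_body_mass > 0:
            raise ValueError(f"max_body_mass must be > 0 for guild {self.name!r}")


class FoodWeb:
    """Guilds, feeding links and fixed bioenergetic coefficients.

    Parameters
    ----------
    guilds
        Ordered guild list; exactly one ``detritus`` node and at least
        one ``producer`` are required.
    links
        ``(consumer, resource)`` name pairs.  Consumers must have role
        ``consumer``; resources may be any node (detritus as a resource
        is detritivory).
    e
        Assimilation efficiency per link, in (0, 1]; keys are the link
        pairs.  Missing links default to ``default_e``.
    s
        Exudation fraction per producer name, in [0, 1).
    ua
        Activity-respiration coefficient per consumer name, in (0, 1];
        ``1`` disables activity respiration.
    """

    def __init__(
        self,
        guilds: Sequence[Guild],
        links: Iterable[tuple[str, str]],
        e: dict[tuple[str, str], float] | None = None,
        s: dict[str, float] | None = None,
        ua: dict[str, float] | None = None,
        default_e: float = 1.0,
    ) -> None:
        self.guilds = list(guilds)
        names = [g.name for g in self.guilds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate guild names")
        self._index = {n: i for i, n in enumerate(names)}

        roles = np.array([g.role for g in self.guilds])
        detr = np.flatnonzero(roles == "detritus")
        if detr.size != 1:
            raise ValueError("a food web needs exactly one detritus node")
        if not np.any(roles == "producer"):
            raise ValueError("a food web needs at least one producer")
        self.detritus_index = int(detr[0])
        self.producer_indices = np.flatnonzero(roles == "producer")
        self.consumer_indices = np.flatnonzero(roles == "consumer")

        raw = [(c, r) for c, r in links]
        if len(set(raw)) != len(raw):
            raise ValueError("duplicate feeding links")
        for c, r in raw:
            if c not in self._index or r not in self._index:
                raise ValueError(f"link ({c!r}, {r!r}) references unknown guild")
            if self.guilds[self._index[c]].role != "consumer":
                raise ValueError(f"link consumer {c!r} is not a consumer guild")
        # canonical order: grouped by consumer (web order), then resource
        raw.sort(key=lambda cr: (self._index[cr[0]], self._index[cr[1]]))
        self.links = raw
        self.link_consumer = np.array([self._index[c] for c, _ in raw], dtype=int)
        self.link_resource = np.array([self._index[r] for _, r in raw], dtype=int)

        linked = set(self.link_consumer.tolist())
        for i in self.consumer_indices:
            if int(i) not in linked:
                raise ValueError(f"consumer {names[i]!r} has no resource")

        e = dict(e or {})
        self.e = np.array([float(e.get(l, default_e)) for l in raw])
        if np.any(self.e <= 0) or np.any(self.e > 1):
            raise ValueError("assimilation efficiencies must lie in (0, 1]")
        s = dict(s or {})
        self.s = np.zeros(len(self.guilds))
        for name, val in s.items():
            if self.guilds[self._index[name]].role != "producer":
                raise ValueError(f"exudation set for non-producer {name!r}")
            self.s[self._index[name]] = float(val)
        if np.any(self.s < 0) or np.any(self.s[self.producer_indices] >= 1):
            raise ValueError("exudation fractions must lie in [0, 1)")
        ua = dict(ua or {})
        self.ua = np.ones(len(self.guilds))
        for name, val in ua.items():
            if self.guilds[self._index[name]].role != "consumer":
                raise ValueError(f"activity respiration set for non-consumer {name!r}")
            self.ua[self._index[name]] = float(val)
        if np.any(self.ua <= 0) or np.any(self.ua > 1):
            raise ValueError("activity-respiration coefficients must lie in (0, 1]")

        # segment pointers for per-consumer sums over the link axis
        # (links are sorted by consumer, so each consumer owns a slice)
        if raw:
            change = np.flatnonzero(np.diff(self.link_consumer)) + 1
            self._seg_ptr = np.concatenate(([0], change))
            seg_of_link = np.zeros(len(raw), dtype=int)
            seg_of_link[self._seg_ptr] = 1
            self._seg_of_link = np.cumsum(seg_of_link) - 1
        else:
            self._seg_ptr = np.zeros(0, dtype=int)
            self._seg_of_link = np.zeros(0, dtype=int)
        # link -> node incidence (dense; webs here are small)
        n = len(self.guilds)
        L = len(raw)
        self._R_res = np.zeros((L, n))
        self._R_res[np.arange(L), self.link_resource] = 1.0
        self._R_cons = np.zeros((L, n))
        self._R_cons[np.arange(L), self.link_consumer] = 1.0
        # egestion routes the unassimilated share of non-detrital intake
        self._detr_coef = (1.0 - self.e) * (self.link_resource != self.detritus_index)

    # -- basic queries ---------------------------------------------------
    @property
    def node_names(self) -> list[str]:
        return [g.name for g in self.guilds]

    @property
    def n_nodes(self) -> int:
        return len(self.guilds)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def index(self, name: str) -> int:
        return self._index[name]

    def links_of(self, consumer: str) -> list[tuple[str, str]]:
        ci = self._index[consumer]
        return [l for l, c in zip(self.links, self.link_consumer) if c == ci]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FoodWeb({self.n_nodes} nodes: {len(self.producer_indices)} producers, "
            f"{len(self.consumer_indices)} consumers, 1 detritus; {self.n_links} links)"
        )


@dataclass
class RateParameters:
    """Free dynamical parameters of the ATN model.

    Arrays are aligned with the web: ``r`` over producers (web order),
    ``um`` over consumers, and ``J``, ``B0``, ``q`` over the canonical
    link order ``web.links``.
    """

    r: np.ndarray  # producer intrinsic growth rates, 1/yr
    K: float  # system-wide carrying capacity, t/km^2
    um: np.ndarray  # consumer metabolic (maintenance) rates, 1/yr
    J: np.ndarray  # per-link maximum ingestion rates, 1/yr
    B0: np.ndarray  # per-link half-saturation biomasses, t/km^2
    q: np.ndarray  # per-link functional-response exponents, >= 0
    um_lower: np.ndarray | None = None  # allometric lower bounds on um

    def __post_init__(self) -> None:
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        self.um = np.atleast_1d(np.asarray(self.um, dtype=float))
        self.J = np.atleast_1d(np.asarray(self.J, dtype=float))
        self.B0 = np.atleast_1d(np.asarray(self.B0, dtype=float))
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.K = float(self.K)
        if self.um_lower is not None:
            self.um_lower = np.atleast_1d(np.asarray(self.um_lower, dtype=float))

    def validate(self, web: FoodWeb) -> None:
        L = web.n_links
        if (
            self.r.shape != (len(web.producer_indices),)
            or self.um.shape != (len(web.consumer_indices),)
            or self.J.shape != (L,)
            or self.B0.shape != (L,)
            or self.q.shape != (L,)
        ):
            raise ValueError("parameter arrays do not match web dimensions")
        if not (
            np.all(self.r > 0)
            and self.K > 0
            and np.all(self.um > 0)
            and np.all(self.J > 0)
            and np.all(self.B0 > 0)
        ):
            raise ValueError("rate parameters must be strictly positive")
        if np.any(self.q < 0):
            raise ValueError("functional-response exponents must be >= 0")
        if self.um_lower is not None and np.any(self.um < self.um_lower):
            raise ValueError("metabolic rates below their lower bounds")


@dataclass
class Trajectory:
    """Deterministic simulation output with the guild-removal record."""

    B: np.ndarray  # (n_years, n_nodes)
    removals: list[tuple[str, int]] = field(default_factory=list)
    # removals: (node name, first year index at which the node is held at 0)


def logistic_growth(B_i: float | np.ndarray, K: float) -> float | np.ndarray:
    """Logistic growth fraction ``G(B) = 1 - B/K``.

    May be negative when ``B > K``; the system-wide carrying capacity
    ``K`` must be strictly positive.
    """
    if not K > 0:
        raise ValueError("carrying capacity K must be > 0")
    return 1.0 - np.asarray(B_i) / K if isinstance(B_i, np.ndarray) else 1.0 - B_i / K


def _fr_weights(B: np.ndarray, params: RateParameters, web: FoodWeb) -> np.ndarray:
    """Per-link saturation weights ``(B_res / B0)^(1+q)`` for states B (m, n).

    Negative resource biomasses are treated as 0 so fractional powers
    stay real.
    """
    Bres = np.maximum(B[:, web.link_resource], 0.0)
    return (Bres / params.B0) ** (1.0 + params.q)


def _fr_fractions(B: np.ndarray, params: RateParameters, web: FoodWeb) -> np.ndarray:
    """Functional-response values F per link for a batch of states (m, L)."""
    if web.n_links == 0:
        return np.zeros((B.shape[0], 0))
    w = _fr_weights(B, params, web)
    denom = 1.0 + np.add.reduceat(w, web._seg_ptr, axis=1)
    return w / denom[:, web._seg_of_link]


def functional_response(
    consumer: str | int, B: np.ndarray, params: RateParameters, web: FoodWeb
) -> np.ndarray:
    """Holling-type feeding fractions of one consumer on its resources.

    Returns ``F_ij`` for each of the consumer's links (canonical link
    order); each value lies in [0, 1) and they sum to < 1.  The exponent
    ``q`` interpolates between type II (q = 0) and type III (q = 1).
    """
    ci = web.index(consumer) if isinstance(consumer, str) else int(consumer)
    if ci not in set(web.link_consumer.tolist()):
        raise ValueError(f"node index {ci} has no feeding links")
    F = _fr_fractions(np.atleast_2d(np.asarray(B, dtype=float)), params, web)[0]
    return F[web.link_consumer == ci]


def drift(
    B: np.ndarray,
    params: RateParameters,
    web: FoodWeb,
    catch: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic biomass rates f(B) for one state or a batch of states.

    ``B`` has shape (n_nodes,) or (m, n_nodes); ``catch`` broadcasts the
    same way (tonnes/km^2/yr, nonzero only where catches apply).  Output
    matches the shape of ``B``.
    """
    B = np.asarray(B, dtype=float)
    single = B.ndim == 1
    B2 = np.atleast_2d(B)
    if B2.shape[1] != web.n_nodes:
        raise ValueError("state length does not match the web")

    F = _fr_fractions(B2, params, web)
    flux = B2[:, web.link_consumer] * params.J * F  # ingestion per link

    rate = np.zeros_like(B2)
    # resource loss and assimilated consumer gain
    rate -= flux @ web._R_res
    gain_coef = web.e * web.ua[web.link_consumer]
    rate += (gain_coef * flux) @ web._R_cons
    # maintenance metabolism
    cons = web.consumer_indices
    rate[:, cons] -= params.um * B2[:, cons]
    # producer logistic growth split between retained growth and exudation
    prod = web.producer_indices
    G = 1.0 - B2[:, prod] / params.K
    grow = params.r * B2[:, prod] * G
    s = web.s[prod]
    rate[:, prod] += grow * (1.0 - s)
    rate[:, web.detritus_index] += (grow * s).sum(axis=1)
    # egestion of unassimilated non-detrital intake into detritus
    rate[:, web.detritus_index] += flux @ web._detr_coef
    if catch is not None:
        rate -= np.asarray(catch, dtype=float)
    return rate[0] if single else rate


def euler_step(
    B: np.ndarray,
    params: RateParameters,
    web: FoodWeb,
    catch: np.ndarray | None = None,
    dt: float = 1.0,
) -> np.ndarray:
    """One explicit Euler step ``B + f(B) dt`` (no positivity clamp)."""
    if not dt > 0:
        raise ValueError("dt must be > 0")
    return B + drift(B, params, web, catch) * dt


def simulate_deterministic(
    B_init: np.ndarray,
    params: RateParameters,
    web: FoodWeb,
    catches: np.ndarray | None = None,
    n_years: int = 18,
) -> Trajectory:
    """Iterate annual Euler steps with guild removal on non-positive updates.

    When a node's predicted biomass falls to <= 0 at year ``t`` it is
    removed from ``t`` onward: biomass held at exactly 0 and the node
    fully decoupled (no feeding, growth, maintenance or catch terms).
    ``catches`` is (n_years, n_nodes); row ``t`` acts as a constant rate
    over the step from year ``t`` to ``t+1``.
    """
    B_init = np.asarray(B_init, dtype=float)
    if np.any(B_init <= 0):
        raise ValueError("initial biomasses must be strictly positive")
    n = web.n_nodes
    out = np.empty((n_years, n))
    out[0] = B_init
    active = np.ones(n, dtype=bool)
    removals: list[tuple[str, int]] = []
    B = B_init.copy()
    for t in range(1, n_years):
        c = None
        if catches is not None:
            c = np.where(active, catches[t - 1], 0.0)
        Bn = euler_step(np.where(active, B, 0.0), params, web, c, dt=1.0)
        newly = active & (Bn <= 0)
        for i in np.flatnonzero(newly):
            removals.append((web.node_names[i], t))
        active &= ~newly
        B = np.where(active, Bn, 0.0)
        out[t] = B
    return Trajectory(B=out, removals=removals)


def count_parameters(
    web: FoodWeb, noise_kind: str = "environmental", estimate_q: bool = True
) -> int:
    """Number of free parameters estimated when calibrating the model.

    Counts one growth rate per producer, the carrying capacity, one
    metabolic rate per consumer, one maximum ingestion rate and one
    half-saturation constant per link, one functional-response exponent
    per link when ``estimate_q``, and one noise scale per node
    (detritus included).  Observation noise additionally estimates one
    initial biomass per node.
    """
    if noise_kind not in ("environmental", "observation"):
        raise ValueError(f"unknown noise kind {noise_kind!r}")
    n = web.n_nodes
    L = web.n_links
    k = len(web.producer_indices) + 1 + len(web.consumer_indices) + 2 * L + n
    if estimate_q:
        k += L
    if noise_kind == "observation":
        k += n
    return k
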