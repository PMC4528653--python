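"""Model-spec serialization, run metadata and distribution comparison.

Model configs are YAML (JSON is a YAML subset and also accepted) with the
fixed schema::

    species: [S0, S4]
    initial_state: [100, 0]
    time_origin: 0.0            # optional
    reactions:
      - id: R40
        reactants: {S0: 1}
        products:  {S4: 1}
        rate: 0.2
        delay:                  # optional; omitted => ordinary reaction
          class: consuming      # or nonconsuming
          family: erlang        # zero | constant | erlang | hypoexponential | tabulated
          params: {shape: 3, rate: 0.2}
    history:                    # optional pending-event queue
      - {reaction_id: R40, due_time: 3.5}

The tabulated family takes ``params: {file: two-column-path}`` (time,
density; whitespace- or comma-delimited) or inline ``grid``/``density``
lists.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .delays import DelayDistribution
from .errors import ModelSpecError, UsageError
from .model import PendingEvent, Reaction, ReactionSystem

__all__ = [
    "load_model_spec",
    "save_model_spec",
    "compare_distributions",
    "DistributionComparison",
    "RunMetadata",
    "model_hash",
]


def _delay_from_spec(spec: dict, rid: str) -> tuple[str, DelayDistribution]:
    cls = spec.get("class")
    if cls not in ("consuming", "nonconsuming"):
        raise ModelSpecError(f"reaction {rid}: delay class must be consuming|nonconsuming")
    family = spec.get("family")
    params = spec.get("params", {}) or {}
    try:
        if family == "zero":
            law = DelayDistribution.zero()
        elif family == "constant":
            law = DelayDistribution.constant(params["s"])
        elif family == "erlang":
            law = DelayDistribution.erlang(params["shape"], params["rate"])
        elif family == "hypoexponential":
            law = DelayDistribution.hypoexponential(params["rates"])
        elif family == "tabulated":
            if "file" in params:
                data = np.loadtxt(params["file"], delimiter=None if "," not in
                                  open(params["file"]).readline() else ",")
                grid, dens = data[:, 0], data[:, 1]
            else:
                grid, dens = params["grid"], params["density"]
            law = DelayDistribution.tabulated(grid, dens)
        else:
            raise ModelSpecError(f"reaction {rid}: unknown delay family {family!r}")
    except KeyError as exc:
        raise ModelSpecError(f"reaction {rid}: missing delay parameter {exc}") from exc
    return cls, law


def _delay_to_spec(rxn: Reaction) -> dict | None:
    if not rxn.is_delayed:
        return None
    law = rxn.delay
    params: dict = {}
    if law.family == "constant":
        params = {"s": law.params["s"]}
    elif law.family == "erlang":
        params = {"shape": law.params["shape"], "rate": law.params["rate"]}
    elif law.family == "hypoexponential":
        params = {"rates": [float(v) for v in law.params["rates"]]}
    elif law.family == "tabulated":
        params = {
            "grid": [float(v) for v in law.params["grid"]],
            "density": [float(v) for v in law.params["density"]],
        }
    return {"class": rxn.delay_class, "family": law.family, "params": params}


def load_model_spec(path) -> ReactionSystem:
    """Read a model config file into a fully constructed :class:`ReactionSystem`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ModelSpecError("model spec must be a mapping")
    missing = [key for key in ("species", "initial_state", "reactions") if key not in doc]
    if missing:
        raise ModelSpecError(f"model spec missing required keys: {missing}")
    reactions = []
    for i, rspec in enumerate(doc["reactions"]):
        rid = rspec.get("id", f"reaction #{i}")
        for key in ("id", "rate"):
            if key not in rspec:
                raise ModelSpecError(f"reaction {rid}: missing key {key!r}")
        if "delay" in rspec and rspec["delay"] is not None:
            delay_class, law = _delay_from_spec(rspec["delay"], rid)
        else:
            delay_class, law = "none", None
        reactions.append(
            Reaction(
                id=rspec["id"],
                reactants=dict(rspec.get("reactants", {}) or {}),
                products=dict(rspec.get("products", {}) or {}),
                rate_constant=float(rspec["rate"]),
                delay_class=delay_class,
                delay=law,
            )
        )
    history = [
        PendingEvent(reaction_id=ev["reaction_id"], due_time=float(ev["due_time"]))
        for ev in doc.get("history", []) or []
    ]
    return ReactionSystem(
        species=list(doc["species"]),
        reactions=reactions,
        initial_state=list(doc["initial_state"]),
        initial_history=history,
        time_origin=float(doc.get("time_origin", 0.0)),
    )


def save_model_spec(system: ReactionSystem, path) -> None:
    """Write a system back to the config schema (inverse of :func:`load_model_spec`)."""
    doc = {
        "species": list(system.species),
        "initial_state": [int(x) for x in system.initial_state],
        "time_origin": float(system.time_origin),
        "reactions": [],
    }
    for r in system.reactions:
        rspec = {
            "id": r.id,
            "reactants": {k: int(v) for k, v in r.reactants.items()},
            "products": {k: int(v) for k, v in r.products.items()},
            "rate": float(r.rate_constant),
        }
        delay = _delay_to_spec(r)
        if delay is not None:
            rspec["delay"] = delay
        doc["reactions"].append(rspec)
    if system.initial_history:
        doc["history"] = [
            {"reaction_id": ev.reaction_id, "due_time": float(ev.due_time)}
            for ev in system.initial_history
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def model_hash(system: ReactionSystem) -> str:
    """Stable short hash of the serialized model (for run metadata)."""
    doc = {
        "species": list(system.species),
        "x0": [int(x) for x in system.initial_state],
        "rxns": [
            (r.id, sorted(r.reactants.items()), sorted(r.products.items()),
             r.rate_constant, r.delay_class, repr(r.delay))
            for r in system.reactions
        ],
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# distribution comparison
# --------------------------------------------------------------------------

@dataclass
class DistributionComparison:
    max_abs_diff: float
    total_variation: float
    chi_square: float
    dof: int

    def as_dict(self) -> dict:
        return asdict(self)


def compare_distributions(
    p: dict, q: dict, n_p: int | None = None, n_q: int | None = None,
    min_expected: float = 5.0,
) -> DistributionComparison:
    """Compare two probability tables over (possibly different) discrete supports.

    Missing states count as probability zero.  ``max_abs_diff`` is the
    largest per-state discrepancy; ``total_variation`` is half the L1
    distance.  The chi-square statistic pools states whose expected count
    falls below ``min_expected``: with only ``n_p`` given it is a
    goodness-of-fit statistic of ``p`` (empirical, ``n_p`` samples) against
    ``q`` (reference); with both sample sizes it is the two-sample statistic.
    Without sample sizes the chi-square field is NaN.
    """
    if not p and not q:
        raise UsageError("both distributions are empty")
    support = sorted(set(p) | set(q))
    pv = np.array([p.get(s, 0.0) for s in support])
    qv = np.array([q.get(s, 0.0) for s in support])
    max_abs = float(np.max(np.abs(pv - qv)))
    tv = 0.5 * float(np.sum(np.abs(pv - qv)))
    chi2, dof = float("nan"), 0
    if n_p is not None and n_q is None:
        obs = pv * n_p
        exp = qv * n_p
        keep = exp >= min_expected
        if np.any(~keep):
            obs = np.append(obs[keep], obs[~keep].sum())
            exp = np.append(exp[keep], exp[~keep].sum())
        good = exp > 0
        chi2 = float(np.sum((obs[good] - exp[good]) ** 2 / exp[good]))
        dof = int(good.sum()) - 1
    elif n_p is not None and n_q is not None:
        op = pv * n_p
        oq = qv * n_q
        exp_min = (op + oq) * min(n_p, n_q) / (n_p + n_q)
        keep = exp_min >= min_expected
        if np.any(~keep):
            op = np.append(op[keep], op[~keep].sum())
            oq = np.append(oq[keep], oq[~keep].sum())
        tot = op + oq
        good = tot > 0
        ratio_p = math.sqrt(n_q / n_p) if (n_p and n_q) else 1.0
        ratio_q = math.sqrt(n_p / n_q) if (n_p and n_q) else 1.0
        chi2 = float(
            np.sum((ratio_p * op[good] - ratio_q * oq[good]) ** 2 / tot[good])
        )
        dof = int(good.sum()) - 1
    return DistributionComparison(max_abs_diff=max_abs, total_variation=tv,
                                  chi_square=chi2, dof=dof)


@dataclass
class RunMetadata:
    """Provenance sidecar written next to every simulation output."""

    model_hash: str
    engine: str
    seed: int | None
    n_runs: int
    t_end: float
    grid: list = field(default_factory=list)
    software_version: str = ""
    wall_time_s: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
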