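"""The 2x2 (Theory of Mind x Goal Alignment) experiment protocol.

Four conditions share the same two agents — Agent A with strong physical
perceptiveness (k = 0.99) and Agent B with weak perceptiveness (k = 0.05) —
on a 60-cell ring with a shared target at cell 30 and private targets at 15
(A) and 45 (B), the chemical field centred on the shared target:

* Model 1 — baseline, no social coupling (alpha = 0, gamma = 0);
* Model 2 — Theory of Mind for the weak agent (alpha_B = 0.2);
* Model 3 — Goal Alignment for both (gamma = 1);
* Model 4 — both capabilities.

A condition batch runs ``n_runs`` replicate dyads with start cells laid out
on a uniform grid (each cell used ``n_runs / N`` times) relative to the
shared target, whose absolute position is randomised per run (preserving
relative target distances) unless ``fixed_targets`` is set.  Metrics:
time-to-target, the label of the target pursued, end-state beliefs, and the
system-level free-energy trace across all agents.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .agent_core import AgentParams, DyadResult
from .belief_space import circ_dist, encode
from .ensemble import EnsembleResult, ReplicateSpec, run_ensemble
from .social import DesireSpec, make_desire_distribution
from .world import WorldConfig

__all__ = [
    "ModelCondition",
    "RunRecord",
    "ConditionResult",
    "build_model_config",
    "run_condition",
    "time_to_target",
    "final_target_distance",
    "belief_convergence_time",
    "target_pursued",
    "summarize",
    "write_outputs",
    "plot_f_sigma",
    "plot_run_raster",
]

logger = logging.getLogger(__name__)

#: target labels in tie-break preference order
TARGET_PREFERENCE = ("shared", "own_private", "partner_private")

# Table of per-model cognitive parameters: (alpha_A, alpha_B, gamma)
_MODEL_TABLE = {
    1: (0.0, 0.0, 0.0),
    2: (0.0, 0.2, 0.0),
    3: (0.0, 0.0, 1.0),
    4: (0.0, 0.2, 1.0),
}
_K_STRONG = 0.99
_K_WEAK = 0.05


@dataclass(frozen=True)
class ModelCondition:
    """One cell of the 2x2 design: world, agent parameters, desire layouts."""

    model_id: int
    params_a: AgentParams
    params_b: AgentParams
    world: WorldConfig
    desires_a: DesireSpec
    desires_b: DesireSpec
    epochs: int = 200


def build_model_config(
    model_id: int,
    n_cells: int = 60,
    epochs: int = 200,
    omega: float = 0.1,
    peak_width: float = 2.0,
    gd_rate: float = 5.0,
    gd_steps: int = 30,
) -> ModelCondition:
    """Construct the named condition of the 2x2 design."""
    if model_id not in _MODEL_TABLE:
        raise ValueError(f"model_id must be one of 1..4, got {model_id}")
    alpha_a, alpha_b, gamma = _MODEL_TABLE[model_id]
    targets = {
        "shared": n_cells // 2,
        "a": n_cells // 4,
        "b": (3 * n_cells) // 4,
    }
    world = WorldConfig(n_cells=n_cells, center=targets["shared"], targets=targets, omega=omega)
    params_a = AgentParams(k=_K_STRONG, alpha=alpha_a, gamma=gamma,
                           gd_rate=gd_rate, gd_steps=gd_steps)
    params_b = AgentParams(k=_K_WEAK, alpha=alpha_b, gamma=gamma,
                           gd_rate=gd_rate, gd_steps=gd_steps)
    desires_a = DesireSpec(shared_peaks=(targets["shared"],), private_peaks=(targets["a"],),
                           peak_width=peak_width, gamma=gamma)
    desires_b = DesireSpec(shared_peaks=(targets["shared"],), private_peaks=(targets["b"],),
                           peak_width=peak_width, gamma=gamma)
    return ModelCondition(model_id=model_id, params_a=params_a, params_b=params_b,
                          world=world, desires_a=desires_a, desires_b=desires_b,
                          epochs=epochs)


@dataclass
class RunRecord:
    """One run's trajectory plus the world it ran in."""

    run_index: int
    model_id: int
    cfg: WorldConfig
    start: int
    dyad: DyadResult

    @property
    def epochs(self) -> int:
        return self.dyad.psi.shape[0] - 1

    def trajectory(self, agent: str) -> np.ndarray:
        return self.dyad.psi[:, _agent_col(agent)]

    def final_belief(self, agent: str, kind: str = "own") -> np.ndarray:
        state = self.dyad.final_a if agent == "a" else self.dyad.final_b
        return state.b_own if kind == "own" else state.b_partner


@dataclass
class ConditionResult:
    """A batch of runs for one condition plus the pooled ensemble scoring."""

    condition: ModelCondition
    records: list
    ensemble: EnsembleResult


def _agent_col(agent: str) -> int:
    if agent not in ("a", "b"):
        raise ValueError("agent must be 'a' or 'b'")
    return 0 if agent == "a" else 1


def _shift_spec(spec: DesireSpec, offset: int, n: int) -> DesireSpec:
    return dataclasses.replace(
        spec,
        shared_peaks=tuple((p + offset) % n for p in spec.shared_peaks),
        private_peaks=tuple((p + offset) % n for p in spec.private_peaks),
    )


def _imputed_spec(own: DesireSpec, partner: DesireSpec) -> DesireSpec:
    """Desires an agent attributes to its partner (Goal Alignment applies to both)."""
    return dataclasses.replace(own, private_peaks=partner.private_peaks)


def run_condition(
    cond: ModelCondition,
    n_runs: int,
    epochs: int | None = None,
    base_seed: int = 0,
    fixed_targets: bool = False,
    starts=None,
    k_sigma: float = 1.0,
    record_beliefs: bool = False,
) -> ConditionResult:
    """Run a batch of replicate dyads for one condition.

    Starts are laid out on the uniform grid relative to the shared target
    (``n_runs`` must be divisible by ``n_cells`` unless an explicit
    ``starts`` list of absolute cells is given).  Per-run RNG substreams are
    derived as ``(base_seed, run_index, agent_index)``; target
    randomisation, when on, draws one offset per run from substream index 2.
    """
    epochs = cond.epochs if epochs is None else epochs
    n = cond.world.n_cells
    if starts is None:
        if n_runs % n == 0:
            start_offsets = np.repeat(np.arange(n), n_runs // n)
        elif n % n_runs == 0:
            # scaled-down batch: still uniform, every (n / n_runs)-th cell
            start_offsets = np.arange(0, n, n // n_runs)
        else:
            raise ValueError(
                f"n_runs={n_runs} does not tile n_cells={n} uniformly; "
                "pass an explicit starts list for non-grid batches"
            )
    else:
        if len(starts) != n_runs:
            raise ValueError("starts must have length n_runs")
        start_offsets = None

    replicates = []
    metas = []
    for r in range(n_runs):
        if fixed_targets:
            cfg_r = cond.world
            offset = 0
        else:
            rng_t = np.random.default_rng(np.random.SeedSequence((base_seed, r, 2)))
            offset = int(rng_t.integers(n))
            cfg_r = cond.world.shifted(offset)
        if starts is None:
            start = int((cfg_r.targets["shared"] + start_offsets[r]) % n)
        else:
            start = int(starts[r]) % n
        des_a = _shift_spec(cond.desires_a, offset, n)
        des_b = _shift_spec(cond.desires_b, offset, n)
        b_star_a = make_desire_distribution(des_a, cfg_r)
        b_star_b = make_desire_distribution(des_b, cfg_r)
        imp_a = make_desire_distribution(_imputed_spec(des_a, des_b), cfg_r)
        imp_b = make_desire_distribution(_imputed_spec(des_b, des_a), cfg_r)
        replicates.append(ReplicateSpec(
            cfg=cfg_r, params_a=cond.params_a, params_b=cond.params_b,
            desires_a=b_star_a, desires_b=b_star_b,
            imputed_a=imp_a, imputed_b=imp_b,
            start_a=start, start_b=start,
            seed_a=np.random.SeedSequence((base_seed, r, 0)),
            seed_b=np.random.SeedSequence((base_seed, r, 1)),
        ))
        metas.append((cfg_r, start))

    logger.info("model %d: running %d dyads x %d epochs (seed %d)",
                cond.model_id, n_runs, epochs, base_seed)
    ens = run_ensemble(replicates, epochs, k_sigma=k_sigma, record_beliefs=record_beliefs)
    records = [
        RunRecord(run_index=r, model_id=cond.model_id, cfg=meta[0], start=meta[1], dyad=dyad)
        for r, (meta, dyad) in enumerate(zip(metas, ens.dyads))
    ]
    return ConditionResult(condition=cond, records=records, ensemble=ens)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _own_targets(record: RunRecord, agent: str):
    t = record.cfg.targets
    return [t["shared"], t["a"] if agent == "a" else t["b"]]


def _target_labels(record: RunRecord, agent: str):
    t = record.cfg.targets
    own, other = ("a", "b") if agent == "a" else ("b", "a")
    return {"shared": t["shared"], "own_private": t[own], "partner_private": t[other]}


def time_to_target(record: RunRecord, agent: str, tolerance: int = 1) -> int:
    """First epoch at which the agent is within ``tolerance`` cells of one of
    its own targets (shared or private); ``epochs + 1`` if never reached."""
    traj = record.trajectory(agent)
    n = record.cfg.n_cells
    targets = _own_targets(record, agent)
    d = np.min([circ_dist(traj, t, n) for t in targets], axis=0)
    hits = np.nonzero(d <= tolerance)[0]
    return int(hits[0]) if hits.size else record.epochs + 1


def final_target_distance(record: RunRecord, agent: str) -> int:
    """End-state ring distance from the agent's closest own target.

    This is the individual-performance measure proper: unlike first-passage
    time it is not fooled by a lost agent sweeping across a target band.
    """
    final = int(record.trajectory(agent)[-1])
    n = record.cfg.n_cells
    return int(min(circ_dist(final, t, n) for t in _own_targets(record, agent)))


def belief_convergence_time(record: RunRecord, agent: str,
                            entropy_threshold: float = 1.5) -> int:
    """First epoch from which the own-position belief stays sharp.

    Sharpness is decoded-belief entropy at or below ``entropy_threshold``
    nats (uniform over 60 cells is ~4.09 nats; a clean bimodal belief is
    ~0.7).  Returns ``epochs + 1`` if the belief never settles.  Requires
    the run to have been recorded with ``record_beliefs=True``.
    """
    if record.dyad.belief_history is None:
        raise ValueError("belief_convergence_time needs record_beliefs=True runs")
    hist = record.dyad.belief_history[:, _agent_col(agent), :]
    q = np.exp(hist)
    q /= q.sum(axis=1, keepdims=True)
    ent = -np.sum(q * np.log(q), axis=1)
    below = ent <= entropy_threshold
    idx = below.shape[0]  # sentinel: epochs + 1
    for t in range(below.shape[0] - 1, -1, -1):
        if not below[t]:
            break
        idx = t
    return int(idx)


def target_pursued(record: RunRecord, agent: str) -> str:
    """Label of the target nearest the agent's final position.

    Ties resolve in the preference order shared, own private, partner
    private (a behavioural outcome: the shared goal gets the benefit of the
    doubt on equidistant endings).
    """
    final = int(record.trajectory(agent)[-1])
    n = record.cfg.n_cells
    labels = _target_labels(record, agent)
    dists = {lab: circ_dist(final, pos, n) for lab, pos in labels.items()}
    best = min(dists[lab] for lab in TARGET_PREFERENCE)
    for lab in TARGET_PREFERENCE:
        if dists[lab] == best:
            return lab
    raise AssertionError("unreachable")


def _belief_argmax_label(record: RunRecord, agent: str) -> str:
    """Nearest-target label of the final own-belief argmax cell."""
    b = record.final_belief(agent, "own")
    cell = int(np.argmax(b))
    n = record.cfg.n_cells
    labels = _target_labels(record, agent)
    dists = {lab: circ_dist(cell, pos, n) for lab, pos in labels.items()}
    best = min(dists[lab] for lab in TARGET_PREFERENCE)
    return next(lab for lab in TARGET_PREFERENCE if dists[lab] == best)


def summarize(records, ensemble: EnsembleResult | None = None,
              tolerance: int = 1, window: int = 10) -> dict:
    """Condition summary: per-agent convergence and pursuit metrics, system trace stats.

    End-state beliefs are summarised both as the mean decoded distribution
    across runs and as a pooled histogram of belief argmax cells.
    """
    if not records:
        raise ValueError("at least one record is required")
    n = records[0].cfg.n_cells
    out = {"n_runs": len(records), "model_id": records[0].model_id}
    for agent in ("a", "b"):
        times = np.array([time_to_target(rec, agent, tolerance) for rec in records])
        dists = np.array([final_target_distance(rec, agent) for rec in records])
        sentinel = records[0].epochs + 1
        labels = [target_pursued(rec, agent) for rec in records]
        argmax_labels = [_belief_argmax_label(rec, agent) for rec in records]
        mean_belief = np.mean(
            [encode(rec.final_belief(agent, "own")) for rec in records], axis=0
        )
        argmax_hist = np.bincount(
            [int(np.argmax(rec.final_belief(agent, "own"))) for rec in records],
            minlength=n,
        )
        out[agent] = {
            "time_to_target_mean": float(times.mean()),
            "time_to_target_median": float(np.median(times)),
            "frac_reached": float(np.mean(times < sentinel)),
            "final_target_distance_mean": float(dists.mean()),
            "final_target_distance_median": float(np.median(dists)),
            "target_pursued_frac": {
                lab: float(np.mean([l == lab for l in labels])) for lab in TARGET_PREFERENCE
            },
            "belief_argmax_agreement": float(
                np.mean([pl == bl for pl, bl in zip(labels, argmax_labels)])
            ),
            "mean_end_belief": mean_belief.tolist(),
            "end_belief_argmax_hist": argmax_hist.tolist(),
        }
    if ensemble is not None:
        trace = ensemble.f_sigma
        out["system"] = {
            "f_sigma_first_window_mean": float(trace[:window].mean()),
            "f_sigma_final_window_mean": float(trace[-window:].mean()),
            "f_sigma_final": float(trace[-1]),
        }
    return out


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

def runs_frame(records) -> pd.DataFrame:
    """Long-format per-epoch rows: run, epoch, agent, psi, s_own, a_own, F."""
    rows = []
    for rec in records:
        for col, agent in ((0, "a"), (1, "b")):
            psi = rec.dyad.psi[:, col]
            for t in range(rec.epochs + 1):
                rows.append({
                    "run": rec.run_index,
                    "epoch": t,
                    "agent": agent,
                    "psi": int(psi[t]),
                    "s_own": int(rec.dyad.s[t - 1, col]) if t > 0 else pd.NA,
                    "a_own": int(rec.dyad.a[t - 1, col]) if t > 0 else pd.NA,
                    "f": float(rec.dyad.f[t - 1, col]) if t > 0 else np.nan,
                })
    return pd.DataFrame(rows)


def beliefs_frame(records) -> pd.DataFrame:
    """Final belief vectors, one row per (run, agent, kind), cells as columns."""
    rows = []
    for rec in records:
        for agent in ("a", "b"):
            for kind in ("own", "partner"):
                b = rec.final_belief(agent, kind)
                row = {"run": rec.run_index, "agent": agent, "kind": kind}
                row.update({f"c{i}": v for i, v in enumerate(b)})
                rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: ConditionResult, outdir) -> None:
    """Write runs.csv, beliefs_final.csv, summary.json and f_sigma.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runs_frame(result.records).to_csv(outdir / "runs.csv", index=False)
    beliefs_frame(result.records).to_csv(
        outdir / "beliefs_final.csv", index=False, float_format="%.17g"
    )
    trace = result.ensemble.f_sigma
    pd.DataFrame({
        "epoch": np.arange(trace.size),
        "f_sigma": trace,
        "n_replicates": len(result.records),
    }).to_csv(outdir / "f_sigma.csv", index=False, float_format="%.17g")
    summary = summarize(result.records, result.ensemble)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("wrote outputs to %s", outdir)


# ---------------------------------------------------------------------------
# plotting helpers (qualitative, not figure-exact)
# ---------------------------------------------------------------------------

def plot_f_sigma(traces: dict, path=None):
    """Overlay system free-energy traces, one line per labelled condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, trace in traces.items():
        ax.plot(np.asarray(trace), label=str(label))
    ax.set_xlabel("epoch")
    ax.set_ylabel(r"system free energy $F_\Sigma$")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_run_raster(record: RunRecord, path=None):
    """Positions over epochs for both agents, belief raster behind if recorded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, (col, name) in zip(axes, ((0, "Agent A"), (1, "Agent B"))):
        if record.dyad.belief_history is not None:
            q = np.exp(record.dyad.belief_history[:, col, :])
            q = q / q.sum(axis=1, keepdims=True)
            ax.imshow(q.T, aspect="auto", origin="lower", cmap="viridis")
        ax.plot(record.dyad.psi[:, col], color="white", lw=0.8)
        ax.axhline(record.cfg.targets["shared"], color="red", ls="--", lw=0.6)
        ax.set_title(name)
        ax.set_xlabel("epoch")
    axes[0].set_ylabel("cell")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
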