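"""The iterative pseudo-label generation loop.

Starting from a handful of seed labels per category, each iteration

1. segments every three-band group once per category, prompting the
   segmenter one-vs-rest (the category's points as foreground, every other
   category's points as background),
2. fuses the resulting mask stack by spectral voting,
3. scores each voted pixel's confidence and uncertainty against its
   category's current prompt features (through the trainable projection),
4. gates on confidence >= tau_high and uncertainty <= kappa_high,
5. admits the top gated pixels per category as new foreground prompts and
   ledger entries, and
6. takes one gradient step on the spatial-consistency loss, updating only
   the prompt projection.

Background prompts stay frozen at the seed configuration; foreground
prompt sets grow monotonically.  Every admitted pseudo label is recorded
with the confidence and uncertainty it had at emission, so the gate can be
re-audited after the fact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .confidence import (
    PromptFeatureSet,
    Thresholds,
    batch_confidence,
    total_consistency_loss_and_grad,
)
from .scene_io import (
    BandGroupSequence,
    HyperspectralCube,
    SeedLabelSet,
    decompose_bands,
    normalize_group,
)
from .segmenter import (
    BACKGROUND,
    FOREGROUND,
    PointPrompt,
    PromptProjection,
    PromptSet,
    prompt_projection_step,
)
from .voting import MaskStack, VotedLabelMap, assign, tally


@dataclass(frozen=True)
class IPGConfig:
    """Loop parameters: 50 iterations, one admitted sample per category per
    iteration, and the standard gate thresholds by default."""

    iterations: int = 50
    selections_per_class: int = 1
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_votes: int = 1
    projection_lr: float = 0.01
    normalize_mode: str = "minmax"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.selections_per_class < 1:
            raise ValueError("selections_per_class must be >= 1")


@dataclass(frozen=True)
class LedgerEntry:
    """One admitted pseudo label with its gate statistics at emission."""

    row: int
    col: int
    category: int
    p: float
    u: float
    iteration: int


@dataclass
class IPGState:
    """Mutable loop state: prompts, ledger, projection, latest voted map."""

    prompts: PromptSet
    projection: PromptProjection
    n_classes: int
    seed_pixels: set[tuple[int, int]]
    ledger: list[LedgerEntry] = field(default_factory=list)
    voted: VotedLabelMap | None = None
    iteration: int = 0
    logs: list[dict] = field(default_factory=list)

    def ledger_pixels(self) -> set[tuple[int, int]]:
        return {(e.row, e.col) for e in self.ledger}


@dataclass(frozen=True)
class PseudoLabelSet:
    """Final ledger with per-category summary counts."""

    entries: tuple[LedgerEntry, ...]

    def counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for e in self.entries:
            out[e.category] = out.get(e.category, 0) + 1
        return out

    def as_pixel_labels(self) -> list[tuple[int, int, int]]:
        return [(e.row, e.col, e.category) for e in self.entries]

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row", "col", "category", "p", "u", "iteration"])
            for e in self.entries:
                writer.writerow([e.row, e.col, e.category,
                                 f"{e.p:.10f}", f"{e.u:.10f}", e.iteration])

    @classmethod
    def load_csv(cls, path: str | Path) -> "PseudoLabelSet":
        entries = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                entries.append(LedgerEntry(
                    row=int(rec["row"]), col=int(rec["col"]),
                    category=int(rec["category"]), p=float(rec["p"]),
                    u=float(rec["u"]), iteration=int(rec["iteration"]),
                ))
        return cls(tuple(entries))


def initialize(seeds: SeedLabelSet, n_classes: int) -> IPGState:
    """Build the one-vs-rest prompt configuration from the seed labels.

    For every category, its own seeds are foreground and all other
    categories' seeds are background.  A pixel seeded under two categories
    is rejected, and every category in 1..K must contribute seeds.
    """
    if n_classes < 2:
        raise ValueError("the one-vs-rest prompt scheme needs K >= 2")
    by_cat = seeds.by_category()
    missing = sorted(set(range(1, n_classes + 1)) - set(by_cat))
    if missing:
        raise ValueError(f"categories without seed labels: {missing}")
    pixel_owner: dict[tuple[int, int], int] = {}
    for r, c, k in seeds.entries:
        if (r, c) in pixel_owner and pixel_owner[(r, c)] != k:
            raise ValueError(
                f"seed pixel ({r}, {c}) claimed by categories "
                f"{pixel_owner[(r, c)]} and {k}"
            )
        pixel_owner[(r, c)] = k
    prompts = PromptSet()
    dim = None
    for cat in range(1, n_classes + 1):
        for r, c in by_cat[cat]:
            prompts.add(cat, PointPrompt(r, c, FOREGROUND, "seed"))
        for other in range(1, n_classes + 1):
            if other == cat:
                continue
            for r, c in by_cat[other]:
                prompts.add(cat, PointPrompt(r, c, BACKGROUND, "seed"))
    return IPGState(
        prompts=prompts,
        projection=PromptProjection.identity(1),  # resized on first iteration
        n_classes=n_classes,
        seed_pixels=seeds.pixels(),
    )


def _ensure_projection(state: IPGState, dim: int) -> None:
    if state.projection.weight.shape[0] != dim:
        state.projection = PromptProjection.identity(dim)


def run_iteration(state: IPGState, groups_norm: list[np.ndarray], backend,
                  config: IPGConfig) -> IPGState:
    """Advance the loop by one segment/vote/score/gate/select/train round."""
    t = state.iteration + 1
    k = state.n_classes
    n_groups = len(groups_norm)
    h, w = groups_norm[0].shape[:2]

    # 1. segment every (group, category)
    decisions = np.zeros((n_groups, k, h, w), dtype=bool)
    for cat in range(1, k + 1):
        cat_prompts = state.prompts.for_category(cat)
        for j, img in enumerate(groups_norm):
            decisions[j, cat - 1] = backend.segment(img, cat_prompts).mask
    # 2. spectral voting
    voted = assign(tally(MaskStack(decisions)), min_votes=config.min_votes)
    state.voted = voted

    # 3-4. confidence, uncertainty, gate on the feature field of the middle group
    field_img = groups_norm[n_groups // 2]
    feats = backend.embed(field_img).embedding
    _ensure_projection(state, feats.shape[2])
    weight = state.projection.weight
    feats_proj = feats @ weight.T

    taken = state.prompts.all_pixels()
    thresholds = config.thresholds
    gated_raw_feats: list[np.ndarray] = []
    prompt_raw_feats: list[np.ndarray] = []
    selected: list[LedgerEntry] = []
    gate_stats: dict[int, int] = {}
    for cat in range(1, k + 1):
        fg = state.prompts.foreground(cat)
        prompt_raw = np.stack([feats[p.row, p.col] for p in fg])
        prompt_raw_feats.append(prompt_raw)
        prompt_set = PromptFeatureSet(prompt_raw @ weight.T)

        cand_mask = voted.labels.labels == cat
        rows, cols = np.nonzero(cand_mask)
        keep = [i for i, (r, c) in enumerate(zip(rows, cols))
                if (int(r), int(c)) not in taken]
        if not keep:
            gated_raw_feats.append(np.empty((0, feats.shape[2])))
            gate_stats[cat] = 0
            continue
        rows, cols = rows[keep], cols[keep]
        p_vec, u_vec = batch_confidence(feats_proj[rows, cols], prompt_set)
        gate = (p_vec >= thresholds.tau_high) & (u_vec <= thresholds.kappa_high)
        gate_stats[cat] = int(gate.sum())
        gated_raw_feats.append(feats[rows[gate], cols[gate]])

        g_rows, g_cols = rows[gate], cols[gate]
        g_p, g_u = p_vec[gate], u_vec[gate]
        order = np.lexsort((g_cols, g_rows, -g_p))
        for idx in order[: config.selections_per_class]:
            selected.append(LedgerEntry(
                row=int(g_rows[idx]), col=int(g_cols[idx]), category=cat,
                p=float(g_p[idx]), u=float(g_u[idx]), iteration=t,
            ))

    # 5. admit selections (voting makes per-category candidates disjoint,
    #    but keep the one-category-per-pixel invariant defensive)
    chosen: dict[tuple[int, int], LedgerEntry] = {}
    for entry in selected:
        key = (entry.row, entry.col)
        best = chosen.get(key)
        if best is None or (entry.p, -entry.category) > (best.p, -best.category):
            chosen[key] = entry
    for entry in chosen.values():
        state.prompts.add(entry.category,
                          PointPrompt(entry.row, entry.col, FOREGROUND,
                                      f"pseudo@{t}"))
        state.ledger.append(entry)

    # 6. one projection step on the total consistency loss
    loss = float("nan")
    if k >= 2:
        loss, grad = total_consistency_loss_and_grad(
            weight, gated_raw_feats, prompt_raw_feats
        )
        state.projection = prompt_projection_step(
            state.projection, grad, config.projection_lr
        )

    state.iteration = t
    added = {e.category: 1 for e in chosen.values()}
    state.logs.append({
        "iteration": t,
        "added": sum(added.values()),
        "gated": gate_stats,
        "mean_p": float(np.mean([e.p for e in chosen.values()])) if chosen else None,
        "loss": loss,
        "ledger_size": len(state.ledger),
    })
    return state


def run(cube: HyperspectralCube, seeds: SeedLabelSet, backend,
        config: IPGConfig) -> tuple[PseudoLabelSet, VotedLabelMap, IPGState]:
    """Run the full loop for ``config.iterations`` rounds.

    Deterministic given the config seed and a deterministic backend: two
    runs with identical inputs produce identical ledgers.
    """
    groups = decompose_bands(cube)
    groups_norm = [normalize_group(g, mode=config.normalize_mode)
                   for g in groups.groups]
    n_classes = max(seeds.by_category())
    state = initialize(seeds, n_classes)
    for _ in range(config.iterations):
        state = run_iteration(state, groups_norm, backend, config)
    assert state.voted is not None
    return PseudoLabelSet(tuple(state.ledger)), state.voted, state
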