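"""Monte Carlo tree search over SMILES tokens with virtual loss.

The tree's nodes are token prefixes.  Selection descends by the PUCT-style
score

    S_i = R_i / (v_i + w_i) + C * P_i * sqrt(v_p + w_p) / (1 + v_i + w_i)

where R_i is the cumulative reward, v_i the completed visit count, w_i the
virtual (in-flight) visit count, and P_i the language-model prior of the
token.  Virtual loss — incrementing w along the selected path before the
evaluation finishes — makes concurrent selections spread across the tree:
a node with an in-flight evaluation has larger denominators and scores
lower.  For an unvisited node (v + w = 0) the exploitation term is defined
as 0, so the prior drives first visits.

A rollout samples a completion of the leaf's prefix from the prior,
validates it as a molecule, scores it with the (cached) photophysics
oracle and the reward function, and backpropagates.  Invalid strings and
failed evaluations backpropagate reward 0 — the tree learns to avoid them —
but only oracle evaluations of new valid molecules consume the budget.

The coordinator owns the tree: selection (with virtual-loss application)
and backpropagation are serialized; with ``n_workers > 1`` up to that many
oracle evaluations run concurrently in a thread pool.  Single-worker runs
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import csv
import math
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    ExpansionError,
    InputError,
    LedgerFormatError,
    SearchStateError,
)
from .molecule_io import Molecule, parse_smiles
from .oracle import CachedEvaluator, Evaluator
from .prior import PriorModel, detokenize
from .reward import PhotophysicalProfile, RewardParams, STATUS_OK, total_reward


@dataclass
class SearchNode:
    """One tree node: a token prefix plus search statistics."""

    token: str
    prefix: tuple[str, ...]
    prior: float = 1.0          # P_i from the language model
    reward_sum: float = 0.0     # R_i
    visits: int = 0             # v_i
    virtual: int = 0            # w_i
    children: dict[str, "SearchNode"] = field(default_factory=dict)
    expanded: bool = False

    def is_terminal(self, end_token: str) -> bool:
        return bool(self.prefix) and self.prefix[-1] == end_token


@dataclass(frozen=True)
class SearchConfig:
    """Search hyperparameters; ``c`` defaults to the exploration constant 4."""

    budget: int                     # completed oracle evaluations of valid molecules
    c: float = 4.0
    n_workers: int = 1
    max_len: int = 82
    seed: int = 0
    expansion_floor: float = 1e-4   # prune children with prior below this
    max_rollouts: int | None = None  # cap when the grammar is smaller than budget
    enforce_elements: bool = True

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise InputError("budget must be >= 1")
        if self.c <= 0:
            raise InputError("exploration constant must be positive")
        if self.n_workers < 1:
            raise InputError("n_workers must be >= 1")

    @property
    def rollout_cap(self) -> int:
        return self.max_rollouts if self.max_rollouts is not None else 20 * self.budget


@dataclass(frozen=True)
class CandidateRecord:
    """One unique valid molecule from a run: the unit of the ledger."""

    molecule: Molecule
    profile: PhotophysicalProfile
    reward: float
    generation_index: int  # 1-based order of completed evaluation


def selection_score(node: SearchNode, v_p: int, w_p: int, c: float) -> float:
    """PUCT-with-virtual-loss score of a child node."""
    n = node.visits + node.virtual
    exploit = node.reward_sum / n if n > 0 else 0.0
    explore = c * node.prior * math.sqrt(v_p + w_p) / (1 + n)
    return exploit + explore


def select_leaf(root: SearchNode, config: SearchConfig,
                end_token: str = "$") -> list[SearchNode]:
    """Descend by argmax score to an unexpanded or terminal node.

    Virtual loss (w += 1) is applied to every node on the returned path,
    atomically with the selection, so a subsequent selection before any
    backpropagation sees the increased denominators.
    """
    path = [root]
    node = root
    while node.expanded and node.children and not node.is_terminal(end_token):
        v_p, w_p = node.visits, node.virtual
        # max over score; ties broken by child insertion order, which is
        # vocabulary order (expand iterates the vocabulary)
        best, best_score = None, -math.inf
        for child in node.children.values():
            s = selection_score(child, v_p, w_p, config.c)
            if s > best_score:
                best, best_score = child, s
        node = best
        path.append(node)
    for n in path:
        n.virtual += 1
    return path


def expand(node: SearchNode, model: PriorModel,
           floor: float = 1e-4) -> SearchNode:
    """Create one child per vocabulary token with the model's prior.

    Children whose prior falls below ``floor`` are pruned; the retained
    priors are renormalized.  The begin token is never a child.
    """
    end_token = model.vocab.end_token
    if node.is_terminal(end_token):
        raise ExpansionError("cannot expand a terminal node")
    if node.expanded:
        raise ExpansionError("node already expanded")
    probs = model.next_token_distribution(list(node.prefix))
    keep = [(tok, float(p)) for tok, p in zip(model.vocab.tokens, probs)
            if p >= floor and tok != model.vocab.begin_token]
    mass = sum(p for _, p in keep)
    if mass <= 0:
        raise ExpansionError("no child survives the prior floor")
    for tok, p in keep:
        node.children[tok] = SearchNode(
            token=tok, prefix=node.prefix + (tok,), prior=p / mass)
    node.expanded = True
    return node


def backpropagate(path: list[SearchNode], reward: float) -> None:
    """Add ``reward`` and one visit to every node on the path; release the
    virtual loss applied at selection time."""
    if not (0.0 <= reward <= 1.0):
        raise InputError(f"reward {reward} outside [0, 1]")
    for node in path:
        if node.virtual < 1:
            raise SearchStateError(
                f"virtual-visit underflow at node {node.token!r}")
    for node in path:
        node.reward_sum += reward
        node.visits += 1
        node.virtual -= 1


@dataclass
class SearchState:
    """Mutable run state shared by rollouts: oracle cache, ledger, rng."""

    model: PriorModel
    oracle: CachedEvaluator
    params: RewardParams
    config: SearchConfig
    rng: np.random.Generator
    records: list[CandidateRecord] = field(default_factory=list)
    by_canonical: dict[str, CandidateRecord] = field(default_factory=dict)
    parse_cache: dict[str, Molecule | None] = field(default_factory=dict)
    n_rollouts: int = 0

    def parse(self, text: str) -> Molecule | None:
        if text in self.parse_cache:
            return self.parse_cache[text]
        try:
            mol = parse_smiles(text, enforce_elements=self.config.enforce_elements)
        except Exception:
            mol = None
        self.parse_cache[text] = mol
        return mol


def rollout(node: SearchNode, state: SearchState) -> tuple[CandidateRecord | None, float]:
    """Complete the node's prefix, evaluate, and score.

    Invalid SMILES and failed evaluations return reward 0 and no record.
    A duplicate of an already-seen canonical SMILES recomputes its reward
    from the oracle cache but is not issued a new generation index.
    """
    completion = state.model.sample_completion(
        list(node.prefix), state.config.max_len, state.rng)
    if not completion.terminated:
        return None, 0.0
    mol = state.parse(completion.text)
    if mol is None:
        return None, 0.0
    existing = state.by_canonical.get(mol.smiles_canonical)
    if existing is not None:
        return existing, total_reward(existing.profile, state.params)
    profile = state.oracle(mol)
    r = total_reward(profile, state.params)
    if not profile.ok:
        return None, 0.0
    record = CandidateRecord(
        molecule=mol, profile=profile, reward=r,
        generation_index=len(state.records) + 1)
    state.records.append(record)
    state.by_canonical[mol.smiles_canonical] = record
    return record, r


def search(model: PriorModel, oracle: Evaluator, params: RewardParams,
           config: SearchConfig) -> list[CandidateRecord]:
    """Run select → expand → rollout → backpropagate until ``budget`` unique
    valid molecules are evaluated (or the rollout cap is hit).

    Returns the deduplicated ledger in generation order.  Single-worker
    runs are deterministic under a fixed seed; multi-worker runs keep up to
    ``n_workers`` evaluations in flight under virtual loss.
    """
    cached = oracle if isinstance(oracle, CachedEvaluator) else CachedEvaluator(oracle)
    state = SearchState(
        model=model, oracle=cached, params=params, config=config,
        rng=np.random.default_rng(config.seed))
    begin = model.vocab.begin_token
    end = model.vocab.end_token
    root = SearchNode(token=begin, prefix=(begin,))

    def step_serial() -> None:
        path = select_leaf(root, config, end)
        leaf = path[-1]
        if not leaf.is_terminal(end) and not leaf.expanded:
            expand(leaf, model, config.expansion_floor)
        _, r = rollout(leaf, state)
        state.n_rollouts += 1
        backpropagate(path, r)

    if config.n_workers == 1:
        while (len(state.records) < config.budget
               and state.n_rollouts < config.rollout_cap):
            step_serial()
        return list(state.records)

    # Parallel: the coordinator serializes selection/virtual loss, sampling,
    # deduplication and backpropagation; only oracle evaluations (the
    # expensive stage in real deployments) run on the pool.
    with ThreadPoolExecutor(max_workers=config.n_workers) as pool:
        in_flight: dict = {}
        while True:
            while (len(in_flight) < config.n_workers
                   and len(state.records) + len(in_flight) < config.budget
                   and state.n_rollouts < config.rollout_cap):
                path = select_leaf(root, config, end)
                leaf = path[-1]
                if not leaf.is_terminal(end) and not leaf.expanded:
                    expand(leaf, model, config.expansion_floor)
                completion = model.sample_completion(
                    list(leaf.prefix), config.max_len, state.rng)
                state.n_rollouts += 1
                fut = pool.submit(_evaluate_completion, completion, state)
                in_flight[fut] = path
            if not in_flight:
                break
            done, _ = wait(in_flight, return_when=FIRST_COMPLETED)
            for fut in done:
                path = in_flight.pop(fut)
                mol, profile = fut.result()
                r = _ledger_update(state, mol, profile)
                backpropagate(path, r)
    return list(state.records)


def _evaluate_completion(completion, state: SearchState):
    """Worker-side stage: parse and evaluate; returns (molecule, profile)."""
    if not completion.terminated:
        return None, None
    mol = state.parse(completion.text)
    if mol is None:
        return None, None
    return mol, state.oracle(mol)


def _ledger_update(state: SearchState, mol, profile) -> float:
    """Coordinator-side stage: dedup, reward, generation index."""
    if mol is None or profile is None or not profile.ok:
        return 0.0
    existing = state.by_canonical.get(mol.smiles_canonical)
    if existing is not None:
        return total_reward(existing.profile, state.params)
    r = total_reward(profile, state.params)
    record = CandidateRecord(
        molecule=mol, profile=profile, reward=r,
        generation_index=len(state.records) + 1)
    state.records.append(record)
    state.by_canonical[mol.smiles_canonical] = record
    return r


# ---------------------------------------------------------------------------
# run ledger CSV

LEDGER_COLUMNS = ["generation_index", "smiles_canonical", "a_w_nm", "a_i",
                  "f_w_nm", "f_i", "reward", "status"]


def write_ledger(records: list[CandidateRecord], path: str | Path) -> None:
    """Write the run ledger CSV (one row per unique valid molecule)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LEDGER_COLUMNS)
        for rec in records:
            p = rec.profile
            writer.writerow([
                rec.generation_index, rec.molecule.smiles_canonical,
                f"{p.a_w:.6g}", f"{p.a_i:.6g}", f"{p.f_w:.6g}", f"{p.f_i:.6g}",
                f"{rec.reward:.10g}", p.status,
            ])


def read_ledger(path: str | Path,
                enforce_elements: bool = True) -> list[CandidateRecord]:
    """Read a run ledger CSV back into candidate records.

    Molecules are reparsed from the canonical SMILES column.  A malformed
    row raises :class:`LedgerFormatError` naming its line number.
    """
    records: list[CandidateRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != LEDGER_COLUMNS:
            raise LedgerFormatError(
                f"unexpected ledger header {reader.fieldnames}")
        for row in reader:
            lineno = reader.line_num
            try:
                mol = parse_smiles(row["smiles_canonical"],
                                   enforce_elements=enforce_elements)
                profile = PhotophysicalProfile(
                    a_w=float(row["a_w_nm"]), a_i=float(row["a_i"]),
                    f_w=float(row["f_w_nm"]), f_i=float(row["f_i"]),
                    status=row["status"])
                records.append(CandidateRecord(
                    molecule=mol, profile=profile,
                    reward=float(row["reward"]),
                    generation_index=int(row["generation_index"])))
            except (TypeError, ValueError, KeyError) as exc:
                raise LedgerFormatError(
                    f"malformed ledger row at line {lineno}: {exc}") from exc
    return records
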