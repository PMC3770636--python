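"""End-to-end analysis: steps vs. Best rank, homoplasy census, report.

The pipeline computes, for every character, its parsimony step count on
the tree and its Best rank on the full matrix (all taxa active), then
correlates the two — overall and stratified by declared state count — with
Spearman's rho and a two-tailed permutation p-value.

Sign convention: rank 1 is the *most* useful character, so the headline
relationship "faster characters are more useful" appears as a NEGATIVE
correlation between steps and rank. The report states this convention
explicitly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .keyrank import RankEntry, mean_key_depth, rank_best
from .matrix import CharacterDef, CharacterMatrix, read_matrix
from .parsimony import StepCount, step_table
from .simulate import SimConfig, simulate_matrix, simulate_yule_tree
from .stats import spearman_rho, two_tailed_p
from .tree import PhyloTree, parse_newick

__all__ = [
    "CorrelationResult",
    "StudyConfig",
    "StudyReport",
    "correlate_steps_vs_rank",
    "stratify_by_state_count",
    "run_study",
    "write_report",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation between steps and Best rank for one set of characters."""

    rho: Optional[float]
    p: Optional[float]
    n: int
    n_excluded: int = 0
    tested: bool = True
    note: str = ""


def _paired(
    step_counts: Sequence[StepCount], rank_entries: Sequence[RankEntry]
) -> tuple[list[float], list[float], int]:
    """Pair steps with ranks by character id, dropping unusable characters."""
    ranks = {e.char_id: e for e in rank_entries}
    xs: list[float] = []
    ys: list[float] = []
    excluded = 0
    for sc in step_counts:
        entry = ranks.get(sc.char_id)
        if entry is None or not entry.usable or sc.unscored:
            excluded += 1
            continue
        xs.append(float(sc.steps))
        ys.append(float(entry.rank))
    return xs, ys, excluded


def correlate_steps_vs_rank(
    step_counts: Sequence[StepCount],
    rank_entries: Sequence[RankEntry],
    n_perm: int = 100_000,
    seed: int = 0,
) -> CorrelationResult:
    """Overall steps-vs-rank correlation over the usable characters.

    Characters unusable for ranking (or never scored on the tree) are
    excluded and counted in ``n_excluded``. Zero rank variance yields an
    untested result with a note, never a silent rho of 0.
    """
    xs, ys, excluded = _paired(step_counts, rank_entries)
    if len(xs) < 3:
        raise ValueError(f"fewer than 3 usable character pairs (got {len(xs)})")
    rho = spearman_rho(xs, ys)
    if math.isnan(rho):
        return CorrelationResult(
            rho=None,
            p=None,
            n=len(xs),
            n_excluded=excluded,
            tested=False,
            note="zero variance in steps or ranks",
        )
    p = two_tailed_p(xs, ys, method="auto", n_perm=n_perm, seed=seed)
    return CorrelationResult(rho=rho, p=p, n=len(xs), n_excluded=excluded)


def stratify_by_state_count(
    step_counts: Sequence[StepCount],
    rank_entries: Sequence[RankEntry],
    characters: Sequence[CharacterDef],
    min_n: int = 5,
    n_perm: int = 100_000,
    seed: int = 0,
) -> dict[int, CorrelationResult]:
    """Steps-vs-rank correlation within each declared state count k.

    Strata with fewer than ``min_n`` usable characters are reported as not
    tested (rho and p None) rather than dropped, mirroring the practice of
    declining to test tiny classes.
    """
    k_of = {c.id: c.k for c in characters}
    strata: dict[int, list[StepCount]] = {}
    for sc in step_counts:
        strata.setdefault(k_of[sc.char_id], []).append(sc)
    out: dict[int, CorrelationResult] = {}
    for k in sorted(strata):
        scs = strata[k]
        xs, ys, excluded = _paired(scs, rank_entries)
        if len(xs) < max(min_n, 3):
            out[k] = CorrelationResult(
                rho=None,
                p=None,
                n=len(xs),
                n_excluded=excluded,
                tested=False,
                note=f"not tested (n = {len(xs)} < {min_n})",
            )
            continue
        rho = spearman_rho(xs, ys)
        if math.isnan(rho):
            out[k] = CorrelationResult(
                rho=None,
                p=None,
                n=len(xs),
                n_excluded=excluded,
                tested=False,
                note="zero variance in steps or ranks",
            )
            continue
        p = two_tailed_p(xs, ys, method="auto", n_perm=n_perm, seed=seed + k)
        out[k] = CorrelationResult(rho=rho, p=p, n=len(xs), n_excluded=excluded)
    return out


@dataclass(frozen=True)
class StudyConfig:
    """What to analyze: either a simulation or files on disk.

    Exactly one of ``sim`` or (``tree_path`` and ``matrix_path``) must be
    given. ``n_perm``, ``stratum_min`` and ``seed`` control the
    correlation machinery; ``key_depth_sample`` bounds the number of taxa
    driven through the greedy key (None = all taxa).
    """

    sim: Optional[SimConfig] = None
    tree_path: Optional[str] = None
    matrix_path: Optional[str] = None
    n_perm: int = 100_000
    stratum_min: int = 5
    seed: int = 0
    key_depth_sample: Optional[int] = 50

    def __post_init__(self) -> None:
        if self.sim is None and (self.tree_path is None or self.matrix_path is None):
            raise ValueError(
                "StudyConfig needs either sim parameters or both "
                "tree_path and matrix_path"
            )
        if self.sim is not None and (self.tree_path or self.matrix_path):
            raise ValueError("give either sim parameters or file paths, not both")


@dataclass
class StudyReport:
    """Everything the analysis computed, serializable as JSON + TSV."""

    n_characters: int
    n_analyzed: int
    n_excluded: int
    mean_steps: float
    n_homoplastic: int
    n_invariant: int
    fraction_homoplastic: float
    overall: CorrelationResult
    by_state_count: dict[int, CorrelationResult]
    per_character: pd.DataFrame
    key_depth: Optional[dict] = None
    populations_differ: bool = False
    sign_convention: str = (
        "Best rank 1 = most useful; faster characters being more useful "
        "appears as negative rho(steps, rank)"
    )
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_characters": self.n_characters,
            "n_analyzed": self.n_analyzed,
            "n_excluded": self.n_excluded,
            "mean_steps": self.mean_steps,
            "n_homoplastic": self.n_homoplastic,
            "n_invariant": self.n_invariant,
            "fraction_homoplastic": self.fraction_homoplastic,
            "overall": asdict(self.overall),
            "by_state_count": {
                str(k): asdict(v) for k, v in self.by_state_count.items()
            },
            "key_depth": self.key_depth,
            "populations_differ": self.populations_differ,
            "sign_convention": self.sign_convention,
            "config": self.config,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _build_per_character(
    matrix: CharacterMatrix,
    step_counts: Sequence[StepCount],
    rank_entries: Sequence[RankEntry],
) -> pd.DataFrame:
    ranks = {e.char_id: e for e in rank_entries}
    rows = []
    for char, sc in zip(matrix.characters, step_counts):
        entry = ranks[char.id]
        rows.append(
            {
                "char_id": char.id,
                "name": char.name,
                "class": char.class_tag,
                "k": char.k,
                "k_obs": sc.k_obs,
                "steps": sc.steps,
                "min_steps": sc.min_steps,
                "max_steps": sc.max_steps,
                "ci": sc.ci,
                "ri": sc.ri,
                "homoplastic": sc.homoplastic,
                "best_score": entry.best_score,
                "best_rank": entry.rank,
                "usable": entry.usable,
            }
        )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full analysis and return a :class:`StudyReport`.

    Simulated mode builds the tree and matrix from ``config.sim``; file
    mode loads them and requires the tree's leaves to be a subset of the
    matrix taxa (steps are counted on the tree's leaves, ranking uses the
    full matrix, and the report flags when the two populations differ).
    Fully deterministic given the seeds.
    """
    config_echo: dict = {
        "n_perm": config.n_perm,
        "stratum_min": config.stratum_min,
        "seed": config.seed,
        "key_depth_sample": config.key_depth_sample,
    }
    if config.sim is not None:
        tree = simulate_yule_tree(
            config.sim.n_taxa, config.sim.birth_rate, seed=config.sim.seed
        )
        matrix, _records = simulate_matrix(tree, config.sim)
        sim_echo = asdict(config.sim)
        sim_echo["state_counts"] = list(sim_echo["state_counts"])
        config_echo["sim"] = sim_echo
    else:
        tree = parse_newick(Path(config.tree_path).read_text())
        matrix = read_matrix(config.matrix_path)
        tree_set = set(tree.leaf_labels)
        matrix_set = set(matrix.taxa)
        only_tree = sorted(tree_set - matrix_set)
        if only_tree:
            only_matrix = sorted(matrix_set - tree_set)
            raise ValueError(
                "tree and matrix taxa are inconsistent; "
                f"only in tree: {only_tree}; only in matrix: {only_matrix}"
            )
        config_echo["tree_path"] = str(config.tree_path)
        config_echo["matrix_path"] = str(config.matrix_path)

    populations_differ = set(tree.leaf_labels) != set(matrix.taxa)

    step_counts = step_table(tree, matrix)
    rank_entries = rank_best(matrix)  # ranking on the full matrix, all taxa active

    overall = correlate_steps_vs_rank(
        step_counts, rank_entries, n_perm=config.n_perm, seed=config.seed
    )
    by_k = stratify_by_state_count(
        step_counts,
        rank_entries,
        matrix.characters,
        min_n=config.stratum_min,
        n_perm=config.n_perm,
        seed=config.seed,
    )

    steps = [sc.steps for sc in step_counts]
    n_chars = len(step_counts)
    key_depth = None
    if config.key_depth_sample is None or config.key_depth_sample > 0:
        summary = mean_key_depth(
            matrix, n_sample=config.key_depth_sample, seed=config.seed
        )
        key_depth = asdict(summary)

    return StudyReport(
        n_characters=n_chars,
        n_analyzed=overall.n,
        n_excluded=overall.n_excluded,
        mean_steps=sum(steps) / n_chars if n_chars else float("nan"),
        n_homoplastic=sum(1 for sc in step_counts if sc.homoplastic),
        n_invariant=sum(1 for sc in step_counts if sc.steps == 0),
        fraction_homoplastic=(
            sum(1 for sc in step_counts if sc.homoplastic) / n_chars
            if n_chars
            else float("nan")
        ),
        overall=overall,
        by_state_count=by_k,
        per_character=_build_per_character(matrix, step_counts, rank_entries),
        key_depth=key_depth,
        populations_differ=populations_differ,
        config=config_echo,
    )


def write_report(report: StudyReport, out_dir: Union[str, Path]) -> None:
    """Write report.json plus per_character.tsv, steps.tsv and ranking.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n")
    table = report.per_character
    table.to_csv(out / "per_character.tsv", sep="\t", index=False)
    table[
        ["char_id", "class", "k_obs", "steps", "min_steps", "max_steps", "ci", "ri", "homoplastic"]
    ].to_csv(out / "steps.tsv", sep="\t", index=False)
    table[["char_id", "class", "k", "best_score", "best_rank", "usable"]].sort_values(
        "best_rank"
    ).to_csv(out / "ranking.tsv", sep="\t", index=False)
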