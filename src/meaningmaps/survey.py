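"""Rater-survey design: patch partitioning, agreement screening, follow-up design.

Two constraints drive the design of the crowd-rating surveys:

* **Condition blinding** — each scene exists in a consistent and an
  inconsistent version differing in a single object.  A rater must never
  see the same scene in both versions (or they could guess the
  manipulation), yet every rater should see both kinds of scene.  This is
  achieved by splitting the scenes into two halves and crossing them with
  condition, giving two patch *subsets*; every rating set is drawn from a
  single subset.

* **Quality screening** — raters who do not follow the instructions are
  identified by their mean pairwise Krippendorff's alpha with co-raters
  of the same patch subset (``R_alpha``) and excluded below a threshold.

The module also builds the follow-up stimulus design in which, per scene,
six condition-neutral coarse patches (two low-rated L, three median M,
one high-rated H) accompany the Con/Incon patches that contain the
manipulated object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import Condition, GridLevel, Patch, RegionBox, overlap_percentage

__all__ = [
    "RatingRecord",
    "RaterSet",
    "RaterAgreement",
    "Exp2Design",
    "split_into_subsets",
    "partition_patches",
    "krippendorff_alpha",
    "pairwise_alpha",
    "screen_raters",
    "build_exp2_design",
]


@dataclass(frozen=True)
class RatingRecord:
    """One Likert rating of one patch by one rater."""

    rater_id: str
    patch_id: str
    value: int

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4, 5, 6):
            raise ValueError(f"rating must be in 1..6, got {self.value}")


@dataclass(frozen=True)
class RaterSet:
    """A block of patches rated together by the same raters."""

    set_id: str
    subset_label: Literal["A", "B"]
    patch_ids: tuple[str, ...]


@dataclass(frozen=True)
class RaterAgreement:
    rater_id: str
    r_alpha: float
    n_pairs: int


@dataclass(frozen=True)
class Exp2Design:
    """Follow-up design: per scene, roles L/L/M/M/M/H plus Con and Incon.

    ``pairs`` lists every (patch_id, context condition) presentation;
    L/M/H patches appear under both context conditions, Con only under
    consistent, Incon only under inconsistent.  ``subsets`` maps subset
    label to the pair indices a rater assigned to that subset rates.
    """

    roles: Mapping[str, Mapping[str, tuple[str, ...]]]  # scene -> role -> patch_ids
    pairs: tuple[tuple[str, Condition], ...]
    subsets: Mapping[str, tuple[int, ...]]  # "A"/"B" -> indices into pairs


# ---------------------------------------------------------------------------
# partitioning


def split_into_subsets(
    patches: Sequence[Patch], seed: int
) -> tuple[list[Patch], list[Patch]]:
    """Split patches into the two condition-blinded subsets.

    Scenes are shuffled (seeded) and halved; subset A holds the consistent
    patches of the first half and the inconsistent patches of the second,
    subset B the complement.  Hence no subset contains any scene in both
    conditions, but each contains both conditions.
    """
    scenes = sorted({p.scene_id for p in patches})
    if len(scenes) % 2:
        raise ValueError("condition-blinded split needs an even number of scenes")
    rng = np.random.default_rng(seed)
    order = [scenes[i] for i in rng.permutation(len(scenes))]
    half_a = set(order[: len(order) // 2])
    sub_a, sub_b = [], []
    for p in patches:
        in_first = p.scene_id in half_a
        consistent = p.condition == Condition.CONSISTENT
        (sub_a if in_first == consistent else sub_b).append(p)
    return sub_a, sub_b


def partition_patches(
    patches: Sequence[Patch], set_size: int, seed: int
) -> list[RaterSet]:
    """Partition all patches into rating sets respecting condition blinding.

    Each set draws its patches from one subset only (seeded shuffle within
    subset, then chunking), so no rater who rates one set ever sees a
    scene in both conditions.
    """
    sub_a, sub_b = split_into_subsets(patches, seed)
    rng = np.random.default_rng(seed + 1)
    sets: list[RaterSet] = []
    for label, subset in (("A", sub_a), ("B", sub_b)):
        if len(subset) % set_size:
            raise ValueError(
                f"set_size {set_size} does not divide subset {label} "
                f"({len(subset)} patches)"
            )
        ids = [subset[i].patch_id for i in rng.permutation(len(subset))]
        for k in range(0, len(ids), set_size):
            sets.append(
                RaterSet(
                    set_id=f"{label}{k // set_size:02d}",
                    subset_label=label,
                    patch_ids=tuple(ids[k : k + set_size]),
                )
            )
    return sets


# ---------------------------------------------------------------------------
# Krippendorff's alpha


def _ordinal_delta_sq(marginals: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Ordinal-metric squared distances from coincidence-matrix marginals."""
    k = len(values)
    delta = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s = marginals[i : j + 1].sum() - (marginals[i] + marginals[j]) / 2.0
            delta[i, j] = delta[j, i] = s * s
    return delta


def krippendorff_alpha(
    units: Iterable[Sequence[float]], metric: str = "interval"
) -> float:
    """Krippendorff's alpha from its definitional coincidence matrix.

    ``units`` yields, per rated unit, the values assigned by the raters
    who rated it (units with fewer than two values are ignored, as they
    contribute no coincidences).  alpha = 1 - D_o / D_e with observed and
    expected disagreement computed from the coincidence matrix.
    """
    units = [np.asarray(u, dtype=float) for u in units]
    units = [u for u in units if u.size >= 2]
    if not units:
        raise ValueError("no units with at least two ratings")
    values = np.unique(np.concatenate(units))
    idx = {v: i for i, v in enumerate(values)}
    k = len(values)
    coincidence = np.zeros((k, k))
    for u in units:
        m = u.size
        for a in range(m):
            for b in range(m):
                if a != b:
                    coincidence[idx[u[a]], idx[u[b]]] += 1.0 / (m - 1)
    n_tot = coincidence.sum()
    marginals = coincidence.sum(axis=1)
    if metric == "interval":
        delta = (values[:, None] - values[None, :]) ** 2
    elif metric == "ordinal":
        delta = _ordinal_delta_sq(marginals, values)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d_o = (coincidence * delta).sum() / n_tot
    d_e = (np.outer(marginals, marginals) * delta).sum() / (n_tot * (n_tot - 1.0))
    if d_e == 0:
        raise ZeroDivisionError(
            "expected disagreement is zero (all shared ratings constant); "
            "alpha undefined"
        )
    return float(1.0 - d_o / d_e)


def pairwise_alpha(
    ratings_a: Sequence[RatingRecord],
    ratings_b: Sequence[RatingRecord],
    metric: str = "interval",
) -> float:
    """Alpha between two raters, restricted to their shared patches."""
    by_a = {r.patch_id: r.value for r in ratings_a}
    by_b = {r.patch_id: r.value for r in ratings_b}
    shared = sorted(set(by_a) & set(by_b))
    if not shared:
        raise ValueError("raters share no rated patches")
    return krippendorff_alpha(
        [(by_a[p], by_b[p]) for p in shared], metric=metric
    )


def screen_raters(
    all_ratings: pd.DataFrame,
    threshold: float = 0.40,
    metric: str = "interval",
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Compute per-rater mean pairwise alpha and screen at a threshold.

    ``all_ratings`` needs columns ``rater_id``, ``patch_id``, ``value``
    and ``set_id``; pairwise alphas are computed only between raters who
    rated the same set (co-raters).  A rater is retained iff their mean
    pairwise alpha (``R_alpha``) exceeds ``threshold``.  Raters with no
    co-raters are excluded from screening and reported with NaN.

    Returns (retained ids, excluded ids, agreement table).
    """
    required = {"rater_id", "patch_id", "value", "set_id"}
    if not required.issubset(all_ratings.columns):
        raise ValueError(f"ratings table needs columns {sorted(required)}")
    per_rater = {
        rid: [RatingRecord(str(rid), str(p), int(v)) for p, v in zip(g["patch_id"], g["value"])]
        for rid, g in all_ratings.groupby("rater_id")
    }
    rater_sets = all_ratings.groupby("rater_id")["set_id"].agg(lambda s: frozenset(s))
    alphas: dict[str, list[float]] = {r: [] for r in per_rater}
    raters = sorted(per_rater)
    for i, ra in enumerate(raters):
        for rb in raters[i + 1 :]:
            if not (rater_sets[ra] & rater_sets[rb]):
                continue
            a = pairwise_alpha(per_rater[ra], per_rater[rb], metric=metric)
            alphas[ra].append(a)
            alphas[rb].append(a)
    rows = []
    retained, excluded = [], []
    for r in raters:
        if alphas[r]:
            r_alpha = float(np.mean(alphas[r]))
            (retained if r_alpha > threshold else excluded).append(r)
        else:
            r_alpha = float("nan")
            excluded.append(r)
        rows.append(RaterAgreement(r, r_alpha, len(alphas[r])))
    table = pd.DataFrame(
        {"rater_id": [a.rater_id for a in rows],
         "R_alpha": [a.r_alpha for a in rows],
         "n_pairs": [a.n_pairs for a in rows]}
    )
    return retained, excluded, table


# ---------------------------------------------------------------------------
# follow-up (Exp 2) stimulus design


def build_exp2_design(
    exp1_ratings: pd.DataFrame,
    patches: Sequence[Patch],
    regions: Mapping[str, RegionBox],
    seed: int,
    con_incon: Mapping[str, tuple[str, str]] | None = None,
) -> Exp2Design:
    """Select per-scene L/M/H patches from first-round coarse ratings.

    Per scene: coarse patches overlapping the critical region are
    excluded; each remaining grid location's ratings are averaged across
    the two conditions; locations are sorted ascending by that average and
    the 2 lowest (L), 1 highest (H) and 3 closest to the median (M) are
    picked.  Median-distance ties break toward the lower rating, then
    lexicographic patch id; top/bottom ties break lexicographically
    (the sort is by (rating, patch_id)).

    ``con_incon`` maps scene -> (con_patch_id, incon_patch_id); by default
    the Con/Incon ids are synthesised as ``{scene}_con`` / ``{scene}_incon``
    placeholders for the manually chosen object patches.

    The presentation pairs (L/M/H under both context conditions, Con under
    consistent, Incon under inconsistent) are split into two equal rater
    subsets such that no subset holds a scene in both conditions.
    """
    coarse = [p for p in patches if p.level == GridLevel.COARSE]
    by_scene: dict[str, list[Patch]] = {}
    for p in coarse:
        by_scene.setdefault(p.scene_id, []).append(p)
    means = exp1_ratings.groupby("patch_id")["value"].mean()

    roles: dict[str, dict[str, tuple[str, ...]]] = {}
    for scene in sorted(by_scene):
        region = regions[scene]
        # one representative patch per grid location (conditions share centres)
        by_loc: dict[tuple[float, float], list[Patch]] = {}
        for p in by_scene[scene]:
            by_loc.setdefault(p.center, []).append(p)
        eligible = []
        for center, ps in by_loc.items():
            if overlap_percentage(ps[0], region) > 0:
                continue
            vals = [means[p.patch_id] for p in ps if p.patch_id in means.index]
            if not vals:
                raise ValueError(f"no ratings for location {center} of {scene}")
            loc_id = min(p.patch_id for p in ps)
            eligible.append((float(np.mean(vals)), loc_id))
        if len(eligible) < 6:
            raise ValueError(
                f"scene {scene}: only {len(eligible)} coarse locations clear of "
                "the critical region; need >= 6"
            )
        eligible.sort()  # (rating, patch_id) — deterministic tie-break
        low = [pid for _, pid in eligible[:2]]
        high = [eligible[-1][1]]
        med = float(np.median([v for v, _ in eligible]))
        middle_pool = eligible[2:-1]
        middle_pool.sort(key=lambda t: (abs(t[0] - med), t[0], t[1]))
        mid = sorted(pid for _, pid in middle_pool[:3])
        if con_incon is not None:
            con_id, incon_id = con_incon[scene]
        else:
            con_id, incon_id = f"{scene}_con", f"{scene}_incon"
        roles[scene] = {
            "L": tuple(low),
            "M": tuple(mid),
            "H": tuple(high),
            "Con": (con_id,),
            "Incon": (incon_id,),
        }

    pairs: list[tuple[str, Condition]] = []
    pair_scene: list[str] = []
    for scene in sorted(roles):
        r = roles[scene]
        for pid in (*r["L"], *r["M"], *r["H"]):
            for cond in (Condition.CONSISTENT, Condition.INCONSISTENT):
                pairs.append((pid, cond))
                pair_scene.append(scene)
        pairs.append((r["Con"][0], Condition.CONSISTENT))
        pair_scene.append(scene)
        pairs.append((r["Incon"][0], Condition.INCONSISTENT))
        pair_scene.append(scene)

    scenes = sorted(roles)
    if len(scenes) % 2:
        raise ValueError("need an even number of scenes for the balanced split")
    rng = np.random.default_rng(seed)
    order = [scenes[i] for i in rng.permutation(len(scenes))]
    half_a = set(order[: len(order) // 2])
    subset_a, subset_b = [], []
    for i, ((_, cond), scene) in enumerate(zip(pairs, pair_scene)):
        in_first = scene in half_a
        consistent = cond == Condition.CONSISTENT
        (subset_a if in_first == consistent else subset_b).append(i)
    return Exp2Design(
        roles=roles,
        pairs=tuple(pairs),
        subsets={"A": tuple(subset_a), "B": tuple(subset_b)},
    )
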