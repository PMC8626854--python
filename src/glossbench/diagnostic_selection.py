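"""Diagnostic image set construction.

The point of the diagnostic set is decorrelation: a set of images on which
*mean* observer judgments are uninformative about ground-truth material,
so that correlating a model with observers measures shared computation
rather than shared accuracy. The pipeline:

1. prescreening — bin images of each material by mean binary response and
   select a quota per bin with shortfall carry-over, starting from the
   most incorrectly judged bin (harvesting ambiguous images);
2. crowd ratings — many observers rate the candidates on a 5-point scale;
   participants are excluded for wrong trial counts or failed catch trials
   (a clearly glossy teapot, a clearly matte sandcastle);
3. final selection — candidates are split into five equal-width bins by
   mean rating and, per material, 10 images are drawn from each of the
   three central bins, giving 60 images (30 per material).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TASK_RANGES = {"binary": (0.0, 1.0), "rating5": (1.0, 5.0)}


def bin_by_mean_response(responses: pd.DataFrame, n_bins: int) -> pd.Series:
    """Assign each image to an equal-width bin of its mean response.

    Bins cover the task's nominal response range (binary: [0,1]; five-point
    rating: [1,5]) and are half-open [lo, hi) with the top bin closed, so a
    mean exactly on an interior edge lands in the higher bin. Returns an
    image_id -> bin index (1..n_bins) Series.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    tasks = responses["task"].unique()
    if len(tasks) != 1 or tasks[0] not in TASK_RANGES:
        raise ValueError(f"responses must be a single numeric task, got {tasks}")
    lo, hi = TASK_RANGES[tasks[0]]
    means = responses.groupby("image_id")["response"].mean().astype(float)
    width = (hi - lo) / n_bins
    idx = np.floor((means - lo) / width).astype(int) + 1
    return idx.clip(1, n_bins).rename("bin")


def select_with_carryover(
    bins: pd.Series,
    targets: list[int],
    order: list[int],
    seed: int = 0,
) -> list[str]:
    """Quota selection with shortfall carry-over.

    Visit bins in ``order`` (conventionally most-incorrect first). If a bin
    holds fewer images than its (carried) target, take them all and add the
    deficit to the next bin's target; otherwise sample the target count at
    random. Whenever total supply suffices, exactly ``sum(targets)`` images
    come back; an infeasible request raises with the remaining deficit.
    """
    if len(targets) != len(order):
        raise ValueError("targets and order must align")
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    remaining = {b: sorted(bins.index[bins == b].tolist()) for b in order}
    carry = 0
    for b, tgt in zip(order, targets):
        want = tgt + carry
        avail = remaining[b]
        if len(avail) <= want:
            selected.extend(avail)
            remaining[b] = []
            carry = want - len(avail)
        else:
            take = sorted(rng.choice(len(avail), size=want, replace=False))
            selected.extend(avail[i] for i in take)
            remaining[b] = [x for i, x in enumerate(avail) if i not in set(take)]
            carry = 0
    # a shortfall in the last visited bin wraps around to earlier surplus
    # bins (revisited in order) so the quota is met whenever supply allows
    while carry > 0:
        progressed = False
        for b in order:
            if carry == 0:
                break
            avail = remaining[b]
            if not avail:
                continue
            take = min(carry, len(avail))
            pick = sorted(rng.choice(len(avail), size=take, replace=False))
            selected.extend(avail[i] for i in pick)
            remaining[b] = [x for i, x in enumerate(avail) if i not in set(pick)]
            carry -= take
            progressed = True
        if not progressed:
            raise ValueError(f"infeasible selection: short by {carry} images after exhausting all bins")
    return selected


def exclude_participants(
    table: pd.DataFrame,
    expected_trials: int,
    teapot_id: str = "catch_teapot",
    sandcastle_id: str = "catch_sandcastle",
) -> pd.DataFrame:
    """Drop observers with wrong trial counts or failed catch trials.

    An observer is excluded if their total trial count differs from
    ``expected_trials``, if they rated the teapot below the two highest
    gloss categories (< 4), or the sandcastle above the two lowest (> 2).
    Catch-trial rows are removed from the returned table.
    """
    counts = table.groupby("observer_id").size()
    keep = set(counts.index[counts == expected_trials])

    def rating_of(obs: str, image: str) -> float | None:
        sel = table[(table["observer_id"] == obs) & (table["image_id"] == image)]
        return float(sel["response"].iloc[0]) if len(sel) else None

    for obs in list(keep):
        tp = rating_of(obs, teapot_id)
        sc = rating_of(obs, sandcastle_id)
        if tp is None or sc is None or tp < 4 or sc > 2:
            keep.discard(obs)
    out = table[table["observer_id"].isin(keep)]
    return out[~out["image_id"].isin({teapot_id, sandcastle_id})].reset_index(drop=True)


def select_final_diagnostic(
    candidates: pd.DataFrame,
    mean_ratings: pd.Series,
    seed: int = 0,
    n_bins: int = 5,
    per_cell: int = 10,
) -> pd.DataFrame:
    """Pick the final diagnostic set from rated candidates.

    Candidates (columns image_id, material) are split into ``n_bins``
    equal-width bins spanning the observed range of candidate mean ratings
    (panel means compress toward the scale midpoint, so nominal-range bins
    would leave the outer bins empty); per material, ``per_cell`` images
    are drawn (seeded, uniformly) from each of the three central bins. Any
    short cell raises an error naming it. Returns a DataFrame
    (image_id, material, bin) with 2 * 3 * per_cell rows.
    """
    ratings = mean_ratings.loc[candidates["image_id"]]
    lo, hi = float(ratings.min()), float(ratings.max())
    width = max((hi - lo) / n_bins, 1e-9)
    bins = (np.floor((mean_ratings - lo) / width).astype(int) + 1).clip(1, n_bins)
    central = [2, 3, n_bins - 1] if n_bins == 5 else list(range(2, n_bins))
    central = sorted(set(central))
    rng = np.random.default_rng(seed)
    rows = []
    cand = candidates.set_index("image_id")
    for material in ("high", "low"):
        ids_mat = cand.index[cand["material"] == material]
        for b in central:
            cell = sorted(i for i in ids_mat if bins.get(i) == b)
            if len(cell) < per_cell:
                raise ValueError(f"cell (material={material}, bin={b}) has only {len(cell)} candidates (< {per_cell})")
            if len(cell) == per_cell:
                chosen = cell
            else:
                take = rng.choice(len(cell), size=per_cell, replace=False)
                chosen = [cell[i] for i in sorted(take)]
            rows += [(i, material, b) for i in chosen]
    return pd.DataFrame(rows, columns=["image_id", "material", "bin"])


def decorrelation_check(
    human_means: pd.Series,
    ground_truth: pd.Series,
    midpoint: float | None = None,
) -> tuple[float, float]:
    """(Pearson r, accuracy) of mean responses against ground truth.

    ``ground_truth`` maps image_id to {"high", "low"} (or 1/0). Accuracy
    thresholds the mean response at the scale midpoint — ratings above it
    count correct for high-gloss images, below for low-gloss; exact ties
    count as incorrect.
    """
    ids = human_means.index
    gt = ground_truth.loc[ids]
    lab = (gt == "high").astype(float) if gt.dtype == object else gt.astype(float)
    m = human_means.to_numpy(dtype=float)
    lab = lab.to_numpy()
    if midpoint is None:
        midpoint = 0.5 if m.max() <= 1.0 else 3.0  # nominal scale midpoint
    r = float(np.corrcoef(m, lab)[0, 1]) if np.std(m) > 1e-12 and np.std(lab) > 1e-12 else 0.0
    correct = np.where(lab > 0.5, m > midpoint, m < midpoint)
    return r, float(correct.mean())
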