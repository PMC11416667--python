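"""Shared fixtures: synthetic colonies grown once per session."""

from __future__ import annotations

import numpy as np
import pytest

from enclavekit import synthetic, tracking


@pytest.fixture(scope="session")
def colony_25c():
    """64-cell rendered colony with the slow (48 +- 13 min) division clock."""
    cfg = synthetic.GeneratorConfig(mean_division=48.0, sd_division=13.0,
                                    n_target=64, seed=7)
    frames, truth = synthetic.grow_rod_colony(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def colony_37c():
    """64-cell rendered colony with the fast (21 +- 6 min) division clock."""
    cfg = synthetic.GeneratorConfig(mean_division=21.0, sd_division=6.0,
                                    n_target=64, seed=7)
    frames, truth = synthetic.grow_rod_colony(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def tracked_25c(colony_25c):
    cfg, frames, truth = colony_25c
    forest, records = tracking.track_masks([f.mask for f in frames],
                                           cfg.pixel_size)
    return cfg, frames, truth, forest, records


def forest_from_truth(truth):
    """Build a LineageForest directly from generator ground truth (used when
    a test should not depend on the tracker)."""
    from enclavekit.tracking import LineageForest, _Track

    forest = LineageForest()
    for frame, recs in enumerate(truth.per_frame):
        for label0, (track, parent, chain) in enumerate(recs):
            if track not in forest.tracks:
                forest.tracks[track] = _Track(track, chain, parent)
            forest.tracks[track].members.append((frame, label0 + 1))
            forest.assignments[(frame, label0 + 1)] = track
    for frame, mother, daughters, _ in truth.divisions:
        forest.divisions.append((frame, mother, daughters))
    return forest


def chain_accuracy(frames, truth, forest, records):
    """Fraction of cells whose tracker chain label matches ground truth."""
    total = wrong = 0
    for f in range(len(frames)):
        table = truth.frame_table(f)
        for r in records[f]:
            total += 1
            if forest.chain_of(f, r.label) != table[r.label][2]:
                wrong += 1
    return 1.0 - wrong / total


def division_sets(truth, forest):
    """(true, detected) division sets as frozensets of (frame, {d labels})."""
    true_set = set()
    for frame, mother, (d1, d2), _ in truth.divisions:
        t2l = {rec[0]: lab + 1 for lab, rec in enumerate(truth.per_frame[frame])}
        true_set.add((frame, frozenset((t2l[d1], t2l[d2]))))
    det_set = set()
    for frame, mother, (t1, t2) in forest.divisions:
        l1 = next(lab for fr, lab in forest.tracks[t1].members if fr == frame)
        l2 = next(lab for fr, lab in forest.tracks[t2].members if fr == frame)
        det_set.add((frame, frozenset((l1, l2))))
    return true_set, det_set
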