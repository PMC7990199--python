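"""High-level phantom studies: weak-label training and deflation sensitivity.

These functions bundle the full experimental loop used to characterize the
method stack on the synthetic cohort: generate a longitudinal phantom suite,
derive personalized-threshold (PTM) air-trapping labels, train the dense
network on one subject pool, evaluate it on the held-out pool, and trace
QAT-versus-deflation curves for every method.  They are the programmatic
equivalent of the pipeline's train/predict/curve stages, returning in-memory
results instead of files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deflation import DeflationCurve, deflation_curve
from .dn import DNConfig, DNNet, make_slice_samples, nested_cv, predict, train_dn
from .evaluation import dice_coefficient
from .phantom import PhantomPair, phantom_suite
from .qat import at_map, qat_ptm, qat_static856
from .volume import BinaryMask, CTVolume, median_filter_3


@dataclass
class PreparedPair:
    """A phantom pair with filtered volumes and its PTM weak label."""

    pair: PhantomPair
    insp_filtered: CTVolume
    exp_filtered: CTVolume
    label: BinaryMask  # PTM AT map (weak label)
    qat_ptm_percent: float
    qat_static_percent: float
    ptm_threshold: float


@dataclass
class WeakLabelStudyResult:
    model: DNNet
    cfg: DNConfig
    record: object
    train_subjects: list[str]
    test_subjects: list[str]
    prepared: dict  # (subject, timepoint) -> PreparedPair
    dice_dn_vs_ptm: list[float] = field(default_factory=list)
    dice_dn_vs_truth: list[float] = field(default_factory=list)
    qat_dn: list[float] = field(default_factory=list)
    qat_ptm: list[float] = field(default_factory=list)
    qat_static: list[float] = field(default_factory=list)
    at_truth_fraction: list[float] = field(default_factory=list)

    @property
    def mean_dice_dn_vs_ptm(self) -> float:
        return float(np.mean(self.dice_dn_vs_ptm))

    @property
    def mean_dice_dn_vs_truth(self) -> float:
        return float(np.mean(self.dice_dn_vs_truth))

    @property
    def qat_dn_deviation(self) -> float:
        """Mean (QAT_DN - ground-truth AT fraction) over held-out pairs, pp."""
        return float(np.mean(np.array(self.qat_dn) - np.array(self.at_truth_fraction)))


def prepare_suite(n_subjects: int, seed: int, timepoints: int = 4) -> dict:
    """Phantom suite with median-filtered volumes and PTM labels per pair."""
    prepared = {}
    for p in phantom_suite(n_subjects, seed=seed, timepoints=timepoints):
        insp_f = median_filter_3(p.insp)
        exp_f = median_filter_3(p.exp)
        res_ptm, ptm = qat_ptm(insp_f, exp_f, p.insp_mask, p.exp_mask)
        label = at_map(exp_f, p.exp_mask, ptm.T)
        res_856 = qat_static856(exp_f, p.exp_mask)
        prepared[(p.subject, p.timepoint)] = PreparedPair(
            pair=p,
            insp_filtered=insp_f,
            exp_filtered=exp_f,
            label=label,
            qat_ptm_percent=res_ptm.qat_percent,
            qat_static_percent=res_856.qat_percent,
            ptm_threshold=ptm.T,
        )
    return prepared


def weak_label_study(
    seed: int,
    n_subjects: int = 8,
    timepoints: int = 4,
    train_slices: int = 160,
    val_slices: int = 48,
    cfg: DNConfig | None = None,
    prepared: dict | None = None,
) -> WeakLabelStudyResult:
    """Train the DN on PTM labels from half the subjects; evaluate on the rest.

    The subject bipartition is the first repetition of the nested 2-fold
    cross-validation scheme.  Held-out evaluation reports Dice against the PTM
    labels (the training target) and against the phantom's mechanistic ground
    truth, plus QAT_DN calibration.
    """
    if prepared is None:
        prepared = prepare_suite(n_subjects, seed=seed, timepoints=timepoints)
    cfg = cfg or DNConfig.desk(seed=seed % (2**31 - 1))
    subjects = sorted({s for s, _ in prepared})
    train_subj, test_subj = nested_cv(subjects, seed=seed)[0]
    pool = []
    for (s, t), d in sorted(prepared.items()):
        if s in train_subj:
            pool += make_slice_samples(d.exp_filtered, d.pair.exp_mask, d.label, cfg, s, t)
    # validation slices for checkpoint selection come from the training
    # subjects' unused slices, never from the held-out pool
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pool))
    train_pool = [pool[i] for i in sorted(perm[:train_slices])]
    val = [pool[i] for i in sorted(perm[train_slices : train_slices + val_slices])]
    model, record = train_dn(train_pool, cfg, val_samples=val or None)

    result = WeakLabelStudyResult(
        model=model, cfg=cfg, record=record,
        train_subjects=list(train_subj), test_subjects=list(test_subj),
        prepared=prepared,
    )
    for (s, t), d in sorted(prepared.items()):
        if s in train_subj:
            continue
        _, at_dn, q = predict(model, d.exp_filtered, d.pair.exp_mask, cfg)
        result.dice_dn_vs_ptm.append(dice_coefficient(at_dn, d.label))
        result.dice_dn_vs_truth.append(dice_coefficient(at_dn, d.pair.at_truth))
        result.qat_dn.append(q.qat_percent)
        result.qat_ptm.append(d.qat_ptm_percent)
        result.qat_static.append(d.qat_static_percent)
        result.at_truth_fraction.append(d.pair.at_fraction_truth)
    return result


def deflation_study(
    prepared: dict,
    model: DNNet | None = None,
    betas=(1.0, 0.9, 0.8, 0.7, 0.6, 0.5),
    methods=("static856", "ptm", "dn"),
    pair_keys=None,
    mode: str = "physical",
) -> list[DeflationCurve]:
    """Deflation-sensitivity curves over selected phantom pairs."""
    methods = [m for m in methods if m != "dn" or model is not None]
    keys = pair_keys if pair_keys is not None else sorted(prepared)
    curves = []
    for key in keys:
        d = prepared[key]
        p = d.pair
        curves.append(
            deflation_curve(
                p.warped_insp, d.insp_filtered, p.insp_mask, p.exp_mask,
                p.jacobian, betas, list(methods), model=model, mode=mode,
            )
        )
    return curves
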