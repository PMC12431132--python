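"""Dataset assembly, balancing, splitting, and the experiment drivers.

Covers the evaluation protocol around the hybrid model: augmentation
that raises the drowsy minority to the alert majority (50%-overlap
re-windowing of the source signals, falling back to small time-axis
image shifts when raw signals are unavailable), a pooled stratified
70/30 split (with a leave-subjects-out alternative that holds out whole
subjects), and the depth-ablation and kernel-comparison drivers.

Balancing before splitting mirrors the reference protocol but leaks
augmented near-duplicates across partitions; ``augment='after_split'``
restricts augmentation to the training partition instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .hybrid import HybridCNNSVM, SVMConfig, fit_svm, grid_search, predict as svm_predict
from .metrics import compute_metrics, confusion, evaluate_predictions
from .models import ConvNetClassifier
from .preprocess import apply_filter, design_bandpass, segment_recording
from .scalogram import ScalogramTransformer
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

META_COLUMNS = ["subject_id", "session_id", "channel", "start_index", "augmented"]


@dataclass
class ScalogramDataset:
    """Images + labels + provenance, optionally with the source segments."""

    images: np.ndarray  # (n, H, W, 3)
    labels: np.ndarray  # (n,) in {0, 1}
    meta: pd.DataFrame  # one row per image, META_COLUMNS
    segments: np.ndarray | None = None  # (n, n_samples) raw filtered signals
    sampling_rate: float = 512.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, int)
        if not (len(self.images) == len(self.labels) == len(self.meta)):
            raise ValueError("images, labels and meta must align")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "ScalogramDataset":
        return ScalogramDataset(
            images=self.images[idx],
            labels=self.labels[idx],
            meta=self.meta.iloc[idx],
            segments=None if self.segments is None else self.segments[idx],
            sampling_rate=self.sampling_rate,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partitioning policy."""

    mode: str = "pooled_random"  # or "leave_subjects_out"
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("pooled_random", "leave_subjects_out"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def make_split(dataset: ScalogramDataset, spec: SplitSpec = SplitSpec()):
    """Disjoint, exhaustive train/test index arrays.

    ``pooled_random`` splits at the scalogram level (stratified by
    label); ``leave_subjects_out`` holds out whole subjects until the
    test partition reaches about ``1 - train_fraction`` of the samples,
    so no subject spans both partitions.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    if spec.mode == "pooled_random":
        idx = np.arange(n)
        tr, te = train_test_split(
            idx, train_size=spec.train_fraction, random_state=spec.seed,
            stratify=dataset.labels if spec.stratified else None,
        )
        return np.sort(tr), np.sort(te)
    subjects = dataset.meta["subject_id"].to_numpy()
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("leave_subjects_out needs at least 2 subjects")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(uniq)
    target = (1 - spec.train_fraction) * n
    test_subjects, held = [], 0
    for s in order:
        if held >= target:
            break
        test_subjects.append(s)
        held += int(np.sum(subjects == s))
    if len(test_subjects) == uniq.size:
        raise ValueError("cannot hold out all subjects")
    mask = np.isin(subjects, test_subjects)
    return np.flatnonzero(~mask), np.flatnonzero(mask)


def _overlap_candidates(dataset: ScalogramDataset, cls: int):
    """50%-overlap windows bridging consecutive same-session segments."""
    meta = dataset.meta
    idx = np.flatnonzero((dataset.labels == cls) & (~meta["augmented"].to_numpy()))
    by_key: dict[tuple, list[int]] = {}
    for i in idx:
        row = meta.iloc[i]
        by_key.setdefault(
            (row["subject_id"], row["session_id"], row["channel"]), []
        ).append(i)
    pairs = []
    for key, members in sorted(by_key.items()):
        members = sorted(members, key=lambda i: meta.iloc[i]["start_index"])
        step = None
        for a, b in zip(members, members[1:]):
            sa, sb = meta.iloc[a]["start_index"], meta.iloc[b]["start_index"]
            step = sb - sa
            if step == dataset.segments.shape[1]:  # truly consecutive
                pairs.append((a, b))
    return pairs


def balance_by_augmentation(
    dataset: ScalogramDataset,
    transformer: ScalogramTransformer | None = None,
    seed: int = 0,
) -> ScalogramDataset:
    """Raise the minority class to the majority size by augmentation.

    With source segments available, new minority samples are scalograms
    of 50%-overlapping windows bridging consecutive segments of the same
    subject/session/channel; otherwise (or when candidates run out)
    existing minority images are shifted along the time axis by a small
    seeded amount.  Original samples are never altered or dropped;
    augmented rows are flagged in the provenance.
    """
    counts = np.bincount(dataset.labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    need = int(counts.max() - counts.min())
    if need == 0:
        return dataset
    minority = int(np.argmin(counts))
    rng = np.random.default_rng(seed)

    new_images, new_segments, new_meta = [], [], []
    if dataset.segments is not None:
        if transformer is None:
            transformer = ScalogramTransformer(sampling_rate=dataset.sampling_rate)
        pairs = _overlap_candidates(dataset, minority)
        order = rng.permutation(len(pairs))
        n_seg = dataset.segments.shape[1]
        for j in order[:need]:
            a, b = pairs[j]
            window = np.concatenate(
                [dataset.segments[a, n_seg // 2:], dataset.segments[b, : n_seg // 2]]
            )
            new_images.append(transformer.transform_one(window).astype(dataset.images.dtype))
            new_segments.append(window)
            row = dataset.meta.iloc[a].copy()
            row["start_index"] = int(row["start_index"]) + n_seg // 2
            row["augmented"] = True
            new_meta.append(row)
    shortfall = need - len(new_images)
    if shortfall > 0:
        pool = np.flatnonzero(dataset.labels == minority)
        picks = rng.choice(pool, size=shortfall, replace=True)
        width = dataset.images.shape[2]
        max_shift = max(1, width // 10)
        for i in picks:
            shift = int(rng.integers(1, max_shift + 1)) * int(rng.choice([-1, 1]))
            new_images.append(np.roll(dataset.images[i], shift, axis=1))
            if dataset.segments is not None:
                new_segments.append(dataset.segments[i])
            row = dataset.meta.iloc[i].copy()
            row["augmented"] = True
            new_meta.append(row)

    images = np.concatenate([dataset.images, np.stack(new_images)])
    labels = np.concatenate([dataset.labels, np.full(need, minority)])
    meta = pd.concat([dataset.meta, pd.DataFrame(new_meta)], ignore_index=True)
    segments = None
    if dataset.segments is not None:
        segments = np.concatenate([dataset.segments, np.stack(new_segments)])
    return ScalogramDataset(images=images, labels=labels, meta=meta,
                            segments=segments, sampling_rate=dataset.sampling_rate)


def build_scalogram_dataset(
    config: SimConfig,
    windows_per_session: int | None = None,
    channels: tuple[str, ...] = ("C3", "C4"),
    transformer: ScalogramTransformer | None = None,
    keep_segments: bool = True,
) -> ScalogramDataset:
    """Simulate a cohort and turn it into labeled scalogram images.

    ``windows_per_session`` caps the number of 30-s windows taken per
    channel of each session (evenly spaced from the start), trading
    dataset size for runtime.
    """
    transformer = transformer or ScalogramTransformer(sampling_rate=config.sampling_rate)
    spec = design_bandpass(sampling_rate=config.sampling_rate)
    images, labels, segments, rows = [], [], [], []
    for sr in simulate_cohort(config):
        rec = apply_filter(sr.recording, spec)
        segs = segment_recording(rec, channels=channels)
        if windows_per_session is not None:
            per_ch: dict[str, int] = {}
            kept = []
            for s in segs:
                if per_ch.get(s.channel, 0) < windows_per_session:
                    kept.append(s)
                    per_ch[s.channel] = per_ch.get(s.channel, 0) + 1
            segs = kept
        for s in segs:
            images.append(transformer.transform_one(
                s.samples,
                source={"subject_id": s.subject_id, "session_id": s.session_id,
                        "channel": s.channel, "start_index": s.start_index},
            ))
            labels.append(s.label)
            if keep_segments:
                segments.append(s.samples.astype(np.float32))
            rows.append({"subject_id": s.subject_id, "session_id": s.session_id,
                         "channel": s.channel, "start_index": s.start_index,
                         "augmented": False})
    return ScalogramDataset(
        images=np.stack(images),
        labels=np.asarray(labels),
        meta=pd.DataFrame(rows, columns=META_COLUMNS),
        segments=np.stack(segments) if keep_segments else None,
        sampling_rate=config.sampling_rate,
    )


def accuracy_gaps(accuracies: dict[str, float]) -> dict[str, float]:
    """Percentage-point gap between the best entry and each other one."""
    best = max(accuracies.values())
    return {k: best - v for k, v in accuracies.items()}


def run_depth_ablation(
    dataset: ScalogramDataset,
    depths: tuple[int, ...] = (1, 2, 3, 5, 10),
    split: SplitSpec = SplitSpec(),
    epochs: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Train one CNN per depth on an identical split and report metrics.

    Infeasible depths (spatial collapse) get a row with the error noted
    instead of aborting the table.
    """
    tr, te = make_split(dataset, split)
    rows = []
    for depth in depths:
        row: dict = {"depth": depth}
        try:
            clf = ConvNetClassifier(depth=depth, epochs=epochs, random_state=seed,
                                    input_shape=dataset.images.shape[1:])
            clf.fit(dataset.images[tr], dataset.labels[tr])
            pred = clf.predict(dataset.images[te])
            rep = compute_metrics(confusion(dataset.labels[te], pred))
            row.update(rep.rounded())
            row["error"] = ""
        except ValueError as exc:
            row.update({m: None for m in
                        ("accuracy", "sensitivity", "specificity", "precision", "f1")})
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("depth")[
        ["accuracy", "sensitivity", "f1", "precision", "specificity", "error"]
    ]


def run_kernel_comparison(
    features: np.ndarray,
    labels: np.ndarray,
    kernels: tuple[str, ...] = ("rbf", "linear", "poly", "sigmoid"),
    split: SplitSpec = SplitSpec(),
    search: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit each SVM kernel on the same feature split and report metrics.

    With ``search`` the head's C/gamma/degree are grid-searched by
    stratified CV on the training partition.  The ``gap`` column is the
    accuracy difference to the best kernel, in percentage points.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels, int)
    meta = pd.DataFrame({
        "subject_id": np.zeros(len(labels), int), "session_id": 0,
        "channel": "", "start_index": 0, "augmented": False,
    })
    holder = ScalogramDataset(
        images=np.zeros((len(labels), 1, 1, 3), np.float32),
        labels=labels, meta=meta)
    tr, te = make_split(holder, split)
    rows = []
    for kernel in kernels:
        if search:
            config, _ = grid_search(features[tr], labels[tr], kernel=kernel, seed=seed)
        else:
            config = SVMConfig(kernel=kernel)
        svm = fit_svm(features[tr], labels[tr], config)
        pred, scores = svm_predict(svm, features[te])
        rep = evaluate_predictions(labels[te], pred, scores)
        rows.append({"kernel": kernel, **rep.rounded(),
                     "C": config.C, "gamma": config.gamma})
    table = pd.DataFrame(rows).set_index("kernel")
    table["gap"] = [accuracy_gaps(table["accuracy"].to_dict())[k] for k in table.index]
    return table


def run_end_to_end(
    seed: int = 0,
    config: SimConfig | None = None,
    windows_per_session: int | None = 4,
    depth: int = 3,
    epochs: int = 50,
    svm: SVMConfig = SVMConfig(),
    split: SplitSpec | None = None,
    augment: str = "before_split",
    shuffle_labels: bool = False,
) -> dict:
    """The full synthetic pipeline: simulate -> scalograms -> CNN -> SVM.

    Returns the test-set :class:`MetricsReport` plus the sample counts.
    ``shuffle_labels`` permutes all labels after augmentation as a
    chance-level control.  ``augment`` is ``'before_split'`` (reference
    protocol; leaks augmented near-duplicates across partitions) or
    ``'after_split'`` (training partition only).
    """
    if augment not in ("before_split", "after_split"):
        raise ValueError("augment must be 'before_split' or 'after_split'")
    config = replace(config or SimConfig(), seed=seed)
    split = split or SplitSpec(seed=seed)
    dataset = build_scalogram_dataset(config, windows_per_session=windows_per_session)
    if augment == "before_split":
        logger.warning("balancing before the split leaks augmented near-duplicates "
                       "across partitions; pass augment='after_split' to avoid this")
        dataset = balance_by_augmentation(dataset, seed=seed)
    if shuffle_labels:
        rng = np.random.default_rng(seed)
        dataset.labels = rng.permutation(dataset.labels)
    tr, te = make_split(dataset, split)
    train, test = dataset.subset(tr), dataset.subset(te)
    if augment == "after_split":
        train = balance_by_augmentation(train, seed=seed)
    clf = HybridCNNSVM(
        cnn=ConvNetClassifier(depth=depth, epochs=epochs, random_state=seed),
        kernel=svm.kernel, C=svm.C, gamma=svm.gamma, degree=svm.degree,
        random_state=seed,
    )
    clf.fit(train.images, train.labels)
    pred = clf.predict(test.images)
    scores = clf.decision_function(test.images)
    report = evaluate_predictions(test.labels, pred, scores)
    return {
        "report": report,
        "n_train": len(train),
        "n_test": len(test),
        "n_total": len(dataset),
        "classifier": clf,
        "dataset": dataset,
        "train_idx": tr,
        "test_idx": te,
        "test_labels": test.labels,
        "test_scores": scores,
    }
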