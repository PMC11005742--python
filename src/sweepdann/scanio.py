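"""File formats, run configuration and the end-to-end scan pipeline.

Handles ms/discoal-style text blocks for simulated haplotypes, phased VCF
for real-genome scans, HDF5 containers for feature datasets and model
checkpoints, TSV/BED prediction output, and the orchestration that stitches
simulate -> featurize -> train -> predict -> evaluate together with cached,
resumable stage artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diagnostics, simdata
from .dann import CLASS_ORDER, DannModel, ModelConfig, ensemble_predict, train_ensemble
from .featengine import (
    FragmentSpec,
    StandardizedDataset,
    featurize_cases,
    minmax_standardize,
)
from .haplotypes import HaplotypeWindow
from .simdata import LabeledCase, ScenarioParams

logger = logging.getLogger(__name__)

LABEL_INDEX = {name: i for i, name in enumerate(CLASS_ORDER)}


@dataclass
class PredictionRecord:
    """One scanned fragment: interval, class probabilities, domain score."""

    chrom: str
    start: int
    end: int
    probs: np.ndarray
    domain_score: float

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.start >= self.end:
            raise ValueError("start must be < end (0-based half-open)")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-6):
            raise ValueError("probabilities must sum to 1")

    @property
    def label(self) -> str:
        return CLASS_ORDER[int(self.probs.argmax())]


# ---------------------------------------------------------------------------
# ms / discoal text format


def write_ms(cases: list[LabeledCase] | list[HaplotypeWindow], path, length: float | None = None):
    """Write replicates as ms-style '//' blocks with positions on [0, 1)."""
    windows, metas = [], []
    for c in cases:
        if isinstance(c, LabeledCase):
            windows.append(c.window)
            metas.append({"label": c.label, "selected_pos": c.selected_pos, "seed": c.seed})
        else:
            windows.append(c)
            metas.append({})
    path = Path(path)
    with path.open("w") as fh:
        n_hap = windows[0].n_hap if windows else 0
        fh.write(f"ms {n_hap} {len(windows)}\n0 0 0\n")
        for win, meta in zip(windows, metas):
            L = length if length is not None else win.length
            tag = " ".join(f"{k}={v}" for k, v in meta.items() if v is not None)
            fh.write(f"\n// {tag}".rstrip() + "\n")
            fh.write(f"segsites: {win.n_sites}\n")
            rel = (win.positions - win.span[0]) / L
            fh.write("positions: " + " ".join(f"{p:.8f}" for p in rel) + "\n")
            for row in win.matrix:
                fh.write("".join(map(str, row)) + "\n")


def read_ms(path, length: float = 1.0, params: ScenarioParams | None = None) -> list[LabeledCase]:
    """Parse ms/discoal text; relative positions are scaled by ``length``.

    Blocks whose '//' line carries ``label=`` metadata come back as fully
    labeled cases; otherwise the label is None-like ('neutral' is *not*
    assumed) and the window alone is populated.
    """
    if params is None:
        params = ScenarioParams(L=length)
    text = Path(path).read_text().splitlines()
    cases: list[LabeledCase] = []
    i = 0
    rep = 0
    while i < len(text):
        line = text[i].strip()
        if not line.startswith("//"):
            i += 1
            continue
        rep += 1
        meta = dict(kv.split("=", 1) for kv in line[2:].split() if "=" in kv)
        try:
            i += 1
            seg_line = text[i].strip()
            assert seg_line.startswith("segsites:")
            segsites = int(seg_line.split()[1])
            if segsites == 0:
                warnings.warn(f"replicate {rep}: zero segregating sites, skipped")
                while i < len(text) and not text[i].strip().startswith("positions:"):
                    i += 1
                i += 1
                continue
            i += 1
            pos_line = text[i].strip()
            assert pos_line.startswith("positions:")
            rel = np.array([float(x) for x in pos_line.split()[1:]])
            assert rel.size == segsites
            rows = []
            i += 1
            while i < len(text) and text[i].strip() and not text[i].startswith("//"):
                rows.append([int(ch) for ch in text[i].strip()])
                i += 1
            matrix = np.array(rows, dtype=np.int8)
            assert matrix.shape[1] == segsites
        except (AssertionError, ValueError, IndexError) as exc:
            raise ValueError(f"malformed ms block at replicate {rep}") from exc
        positions = rel * length
        # ms replicates can carry duplicate positions; jitter to keep order strict
        for j in range(1, positions.size):
            if positions[j] <= positions[j - 1]:
                positions[j] = np.nextafter(positions[j - 1], np.inf)
        win = HaplotypeWindow(matrix, positions, (0.0, length))
        label = meta.get("label")
        sel = meta.get("selected_pos")
        sel = float(sel) if sel not in (None, "None") else None
        if label:
            cases.append(
                LabeledCase(win, label, dataclasses.replace(params, L=length), sel,
                            int(meta["seed"]) if "seed" in meta else None)
            )
        else:
            win.meta["replicate"] = rep
            cases.append(LabeledCase(win, "neutral", dataclasses.replace(params, L=length)))
    return cases


# ---------------------------------------------------------------------------
# VCF input


def read_vcf_phased(path, chrom: str | None = None, region: str | None = None,
                    fold: bool = False) -> HaplotypeWindow:
    """Load phased biallelic SNPs from a VCF into one haplotype matrix.

    Derived-allele polarity comes from the AA (ancestral allele) INFO tag;
    without it, pass ``fold=True`` to use major/minor coding (a warning
    marks the polarization-dependent statistics as folded). Multiallelic
    and unphased records are skipped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    want_chrom, lo, hi = chrom, None, None
    if region:
        if ":" in region:
            want_chrom, span = region.split(":", 1)
            a, b = span.replace(",", "").split("-")
            lo, hi = int(a), int(b)
        else:
            want_chrom = region
    it = vcf  # plain-text VCFs have no index; filter while streaming
    cols, positions = [], []
    skipped = {"multiallelic": 0, "unphased": 0, "monomorphic": 0}
    saw_aa = False
    last_pos = -1
    for v in it:
        if want_chrom and v.CHROM != want_chrom:
            continue
        if (lo is not None and v.POS < lo) or (hi is not None and v.POS > hi):
            continue
        if v.POS < last_pos:
            raise ValueError("VCF is not position-sorted")
        last_pos = v.POS
        if len(v.ALT) != 1 or not v.is_snp:
            skipped["multiallelic"] += 1
            continue
        gts = np.array(v.genotypes)  # (n_samples, 3): a0, a1, phased
        if not np.all(gts[:, 2]):
            skipped["unphased"] += 1
            continue
        hap = gts[:, :2].reshape(-1).astype(np.int8)
        aa = v.INFO.get("AA")
        if aa is not None:
            saw_aa = True
            aa = str(aa).upper()
            if aa == v.ALT[0].upper():
                hap = 1 - hap
            elif aa != v.REF.upper():
                skipped["multiallelic"] += 1
                continue
        elif fold:
            if hap.mean() > 0.5:
                hap = 1 - hap
        if hap.min() == hap.max():
            skipped["monomorphic"] += 1
            continue
        cols.append(hap)
        positions.append(float(v.POS - 1))  # to 0-based
    if cols and not saw_aa and not fold:
        warnings.warn(
            "no AA (ancestral allele) annotation found; REF treated as ancestral. "
            "Pass fold=True for major/minor coding of polarization-dependent statistics."
        )
    if not cols:
        matrix = np.zeros((2, 0), dtype=np.int8)
        win = HaplotypeWindow(matrix, np.empty(0), (0.0, 1.0))
    else:
        matrix = np.stack(cols, axis=1)
        positions = np.asarray(positions)
        for j in range(1, positions.size):
            if positions[j] <= positions[j - 1]:
                positions[j] = np.nextafter(positions[j - 1], np.inf)
        win = HaplotypeWindow(matrix, positions, (0.0, positions[-1] + 1.0))
    win.meta.update({"source": str(path), "skipped": skipped, "folded": fold})
    logger.info("VCF %s: %d sites kept, skipped %s", path, win.n_sites, skipped)
    return win


# ---------------------------------------------------------------------------
# prediction output


def write_predictions(records: list[PredictionRecord], path, fmt: str = "tsv",
                      fingerprint: str = "") -> None:
    """One row per fragment, sorted by (chrom, start); TSV or BED-like."""
    records = sorted(records, key=lambda r: (r.chrom, r.start))
    path = Path(path)
    with path.open("w") as fh:
        if fmt == "tsv":
            fh.write(f"#config_fingerprint={fingerprint}\n")
            cols = ["chrom", "start", "end", "label", "domain_score"] + [
                f"p_{c}" for c in CLASS_ORDER
            ]
            fh.write("\t".join(cols) + "\n")
            for r in records:
                vals = [r.chrom, str(r.start), str(r.end), r.label,
                        f"{r.domain_score:.6f}"] + [f"{p:.6f}" for p in r.probs]
                fh.write("\t".join(vals) + "\n")
        elif fmt == "bed":
            fh.write(f'track name="sweep_classes" description="fingerprint={fingerprint}"\n')
            for r in records:
                score = int(round(1000 * r.probs.max()))
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{score}\t.\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_predictions(path) -> list[PredictionRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or line.startswith("chrom\t"):
            continue
        f = line.split("\t")
        records.append(
            PredictionRecord(f[0], int(f[1]), int(f[2]),
                             np.array([float(x) for x in f[5:10]]), float(f[4]))
        )
    return records


def merge_consecutive(records: list[PredictionRecord]) -> list[tuple]:
    """Optional post-processor: merge touching same-label fragments to regions."""
    out = []
    for r in sorted(records, key=lambda r: (r.chrom, r.start)):
        if out and out[-1][0] == r.chrom and out[-1][3] == r.label and r.start <= out[-1][2]:
            out[-1] = (r.chrom, out[-1][1], max(out[-1][2], r.end), r.label)
        else:
            out.append((r.chrom, r.start, r.end, r.label))
    return out


# ---------------------------------------------------------------------------
# HDF5 containers


def save_dataset(dataset: StandardizedDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("X", data=dataset.X)
        h5.attrs["domain_tag"] = dataset.domain_tag
        h5.create_dataset("stat_names", data=np.array(dataset.stat_names, dtype="S"))
        if dataset.labels is not None:
            h5.create_dataset("labels", data=np.asarray(dataset.labels))
        if dataset.scale is not None:
            h5.create_dataset("scale_min", data=dataset.scale[0])
            h5.create_dataset("scale_max", data=dataset.scale[1])
        h5.attrs["meta_json"] = json.dumps(dataset.meta, default=str)


def load_dataset(path) -> StandardizedDataset:
    import h5py

    with h5py.File(path, "r") as h5:
        X = h5["X"][:]
        names = [s.decode() for s in h5["stat_names"][:]]
        labels = h5["labels"][:] if "labels" in h5 else None
        scale = None
        if "scale_min" in h5:
            scale = (h5["scale_min"][:], h5["scale_max"][:])
        meta = json.loads(h5.attrs.get("meta_json", "[]"))
        return StandardizedDataset(X, names, h5.attrs["domain_tag"], labels, scale, meta)


def save_checkpoint(models: list[DannModel], path, fingerprint: str = "",
                    scale=None, stat_names=None) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["fingerprint"] = fingerprint
        h5.attrs["n_models"] = len(models)
        if stat_names is not None:
            h5.create_dataset("stat_names", data=np.array(stat_names, dtype="S"))
        if scale is not None:
            h5.create_dataset("scale_min", data=scale[0])
            h5.create_dataset("scale_max", data=scale[1])
        for i, model in enumerate(models):
            g = h5.create_group(f"model_{i}")
            g.attrs["config_json"] = json.dumps(dataclasses.asdict(model.config))
            g.attrs["m"] = model.m
            g.attrs["n_stats"] = model.n_stats
            for part, net in (("extractor", model.extractor),
                              ("classifier", model.classifier),
                              ("discriminator", model.discriminator)):
                sub = g.create_group(part)
                for k, v in net.state_dict().items():
                    sub.create_dataset(k, data=v)


def load_checkpoint(path) -> tuple[list[DannModel], dict]:
    import h5py

    models = []
    with h5py.File(path, "r") as h5:
        info = {"fingerprint": h5.attrs.get("fingerprint", "")}
        if "scale_min" in h5:
            info["scale"] = (h5["scale_min"][:], h5["scale_max"][:])
        if "stat_names" in h5:
            info["stat_names"] = [s.decode() for s in h5["stat_names"][:]]
        for i in range(int(h5.attrs["n_models"])):
            g = h5[f"model_{i}"]
            cfg_dict = json.loads(g.attrs["config_json"])
            for key in ("conv_channels",):
                if key in cfg_dict:
                    cfg_dict[key] = tuple(cfg_dict[key])
            cfg = ModelConfig(**cfg_dict)
            model = DannModel(cfg, m=int(g.attrs["m"]), n_stats=int(g.attrs["n_stats"]))
            for part, net in (("extractor", model.extractor),
                              ("classifier", model.classifier),
                              ("discriminator", model.discriminator)):
                state = {k: g[part][k][:] for k in g[part]}
                net.load_state_dict(state)
            models.append(model)
    return models, info


# ---------------------------------------------------------------------------
# run configuration and orchestration


@dataclass
class RunConfig:
    """Serializable configuration for an end-to-end run."""

    params: ScenarioParams = field(default_factory=ScenarioParams)
    target_params: ScenarioParams | None = None
    spec: FragmentSpec = field(default_factory=FragmentSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    per_class: tuple[int, int, int] = (2400, 300, 300)
    backend: str = "fixture"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.target_params is None:
            d["target_params"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["params"] = ScenarioParams(**d["params"])
        if d.get("target_params"):
            d["target_params"] = ScenarioParams(**d["target_params"])
        d["spec"] = FragmentSpec(**d["spec"])
        mc = dict(d["model"])
        if "conv_channels" in mc:
            mc["conv_channels"] = tuple(mc["conv_channels"])
        d["model"] = ModelConfig(**mc)
        d["per_class"] = tuple(d["per_class"])
        return cls(**d)

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def labels_to_int(cases: list[LabeledCase]) -> np.ndarray:
    return np.array([LABEL_INDEX[c.label] for c in cases])


def featurize_split(split: simdata.DatasetSplit, spec: FragmentSpec):
    """Featurize train/val/test; scale fitted on train, applied to val/test."""
    out = {}
    train = featurize_cases([c.window for c in split.train], spec,
                            labels=labels_to_int(split.train))
    train = minmax_standardize(train, "fit")
    out["train"] = train
    for name, cases in (("validation", split.validation), ("test", split.test)):
        ds = featurize_cases([c.window for c in cases], spec, labels=labels_to_int(cases))
        out[name] = minmax_standardize(ds, "apply", scale=train.scale)
    return out


def run_end_to_end(config: RunConfig, outdir, target_cases: list[LabeledCase] | None = None) -> dict:
    """simulate -> featurize -> train -> predict -> evaluate, with caching.

    Stage artifacts are written under ``outdir`` and reused when present
    (delete a file to rerun from that stage). Returns the evaluation report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fp = config.fingerprint()
    save_config(config, outdir / "config.yaml")

    # stage 1: simulate
    sim_path = outdir / "cases.ms"
    if sim_path.exists():
        cases = read_ms(sim_path, length=config.params.L, params=config.params)
        logger.info("simulate: reused %s", sim_path)
    else:
        cases = simdata.generate_cases(config.params, sum(config.per_class),
                                       config.seed, config.backend)
        write_ms(cases, sim_path, length=config.params.L)
    split = simdata.make_splits(cases, config.per_class, seed=config.seed + 1)

    tgt_params = config.target_params or config.params
    if target_cases is None:
        n_target = sum(1 for _ in split.test)
        target_cases = simdata.generate_cases(
            tgt_params, max(n_target // len(simdata.CLASSES), 1),
            config.seed + 7, config.backend)

    # stage 2: featurize
    feat_paths = {k: outdir / f"features_{k}.h5" for k in
                  ("train", "validation", "test", "target")}
    if all(p.exists() for p in feat_paths.values()):
        feats = {k: load_dataset(p) for k, p in feat_paths.items()}
        logger.info("featurize: reused cached features")
    else:
        feats = featurize_split(split, config.spec)
        tgt = featurize_cases([c.window for c in target_cases], config.spec,
                              domain_tag="target", labels=labels_to_int(target_cases))
        feats["target"] = minmax_standardize(tgt, "apply", scale=feats["train"].scale)
        for k, p in feat_paths.items():
            save_dataset(feats[k], p)

    # stage 3: train
    ckpt_path = outdir / "checkpoint.h5"
    if ckpt_path.exists():
        models, _ = load_checkpoint(ckpt_path)
        logger.info("train: reused %s", ckpt_path)
    else:
        models = train_ensemble(feats["train"], feats["validation"], feats["target"],
                                config.model)
        save_checkpoint(models, ckpt_path, fp, feats["train"].scale,
                        feats["train"].stat_names)

    # stage 4: predict
    pred = ensemble_predict(models, feats["test"].X)
    records = [
        PredictionRecord("test", i * int(config.params.L), (i + 1) * int(config.params.L),
                         pred.probs[j], pred.domain_score[j])
        for j, i in enumerate(range(len(pred.probs)))
    ]
    write_predictions(records, outdir / "predictions.tsv", fingerprint=fp)

    # stage 5: evaluate
    y = np.asarray(feats["test"].labels)
    yhat = pred.probs.argmax(axis=1)
    conf = diagnostics.confusion_5class(yhat, y)
    rocs = diagnostics.per_type_rocs(pred.probs, y)
    tgt_pred = ensemble_predict(models, feats["target"].X)
    hist = diagnostics.domain_score_histogram(tgt_pred.domain_score)
    report = {
        "fingerprint": fp,
        "test_accuracy": float(np.mean(yhat == y)),
        "per_class_accuracy": conf["per_class_accuracy"],
        "auc": {k: v["auc"] for k, v in rocs.items()},
        "confusion_counts": conf["counts"].tolist(),
        "target_domain_mass_below_half": hist["mass_below_half"],
    }
    with (outdir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2)
    return report
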