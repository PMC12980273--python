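"""Synthetic pre/post ECoG generation with drug-class spectral signatures.

The generator emulates quiet-wake rodent cortical activity as a sum of
band-limited Gaussian noise components (one per rhythm) over a 1/f
broadband floor, band-limited to the 0.5-35 Hz acquisition passband.  A
*drug signature* scales the power of each band in each channel region
(frontal FP1/FP2, parietal C3/C4, occipital O1/O2) between the pre- and
post-injection phases; a per-record lognormal jitter models
inter-animal variability of the response.  Both phases of a pair share
the same per-animal channel gains, so the post/pre feature ratio
isolates the designed drug effect.

The default signature table mirrors the reference-panel design of the
screening study this package implements (nine agents at one to three
doses each, plus saline: 19 groups).  Its numeric multipliers are an
invented fixture that qualitatively follows the reported per-drug
band/region power changes; they are not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError
from .features import PARTITION_BANDS, _band_sos
from .io import CHANNELS, REGION_OF, EcogRecording, write_recording
from scipy import signal as sps

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta_lf", "beta_hf")
REGION_ORDER: tuple[str, ...] = ("frontal", "parietal", "occipital")

#: Lognormal SD (log scale) of per-animal channel gains shared by a pair.
ANIMAL_GAIN_SD = 0.1

#: Quiet-wake target RMS amplitudes per rhythm, uV.  Low-frequency
#: dominance matches rodent cortical spectra at rest.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 40.0,
    "theta": 30.0,
    "alpha": 15.0,
    "beta_lf": 8.0,
    "beta_hf": 5.0,
}


@dataclass(frozen=True)
class DrugSignature:
    """Designed per-region, per-band power scaling of one drug-dose group."""

    class_id: str
    multipliers: pd.DataFrame  # regions x partition bands, power scale factors
    jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        m = self.multipliers
        if list(m.index) != list(REGION_ORDER) or list(m.columns) != list(BAND_ORDER):
            raise ConfigurationError(
                f"signature {self.class_id!r}: multipliers must be indexed "
                f"{REGION_ORDER} x {BAND_ORDER}"
            )
        if not np.all(m.to_numpy(float) > 0):
            raise ConfigurationError(f"signature {self.class_id!r}: multipliers must be > 0")
        if self.jitter_sd < 0:
            raise ConfigurationError(f"signature {self.class_id!r}: jitter_sd must be >= 0")


def signature(
    class_id: str,
    frontal: Sequence[float],
    parietal: Sequence[float],
    occipital: Sequence[float],
    jitter_sd: float = 0.1,
) -> DrugSignature:
    """Build a signature from three 5-value rows (delta..beta_hf order)."""
    grid = pd.DataFrame(
        [list(frontal), list(parietal), list(occipital)],
        index=list(REGION_ORDER),
        columns=list(BAND_ORDER),
        dtype=float,
    )
    return DrugSignature(class_id=class_id, multipliers=grid, jitter_sd=jitter_sd)


def uniform_signature(class_id: str, value: float = 1.0, jitter_sd: float = 0.1) -> DrugSignature:
    row = [value] * len(BAND_ORDER)
    return signature(class_id, row, row, row, jitter_sd)


def saline_signature(jitter_sd: float = 0.1) -> DrugSignature:
    """All multipliers 1: the control group produces no designed effect."""
    return uniform_signature("NaCl", 1.0, jitter_sd)


def interpolate_signature(
    sig: DrugSignature, strength: float, class_id: str | None = None
) -> DrugSignature:
    """Log-linear interpolation between saline (0) and ``sig`` (1).

    Used for dose-gradient experiments: multipliers are raised to the
    ``strength`` power so that effects scale multiplicatively.
    """
    grid = sig.multipliers ** float(strength)
    return DrugSignature(
        class_id=class_id or f"{sig.class_id}*{strength:g}",
        multipliers=grid,
        jitter_sd=sig.jitter_sd,
    )


def default_signatures(jitter_sd: float = 0.1) -> list[DrugSignature]:
    """The 19-group reference panel fixture (18 drug-dose groups + saline).

    Band order per row: delta, theta, alpha, beta_lf, beta_hf.  Values
    qualitatively follow the reported per-drug median-power changes
    (e.g. broadband decrease for galantamine, strong frontal broadband
    increase for dexmedetomidine); exact magnitudes are invented.
    """
    s = jitter_sd
    return [
        signature("NaCl", [1, 1, 1, 1, 1], [1, 1, 1, 1, 1], [1, 1, 1, 1, 1], s),
        # D2/D3 antagonists: mild/strong uniform power increase
        signature("SLP 30.0", [1.15] * 5, [1.15] * 5, [1.15] * 5, s),
        signature("SLP 100.0", [1.35] * 5, [1.35] * 5, [1.35] * 5, s),
        signature("HAL 0.3", [1.1, 1.1, 1.45, 1.45, 1.1], [1.1] * 5, [1.1] * 5, s),
        signature("HAL 2.0", [1.6] * 5, [1.15] * 5, [1.15, 1.4, 1.4, 1.15, 1.15], s),
        # AChE inhibitor: broadband decrease, alpha/beta-LF persistent
        signature("GAL 1.0", [0.75] * 5, [0.75] * 5, [0.75] * 5, s),
        signature("GAL 3.0", [0.9, 0.9, 0.72, 0.72, 0.9], [0.9, 0.9, 0.72, 0.72, 0.9],
                  [0.9, 0.9, 0.72, 0.72, 0.9], s),
        # M-cholinolytic: dose-shifting regional emphasis
        signature("TRO 0.5", [1.45, 1.35, 1.15, 1.15, 1.15], [1.15] * 5, [1.15] * 5, s),
        signature("TRO 5.0", [1.05, 1.05, 1.4, 1.05, 1.4], [1.05, 1.05, 1.4, 1.05, 1.4],
                  [1.05, 1.05, 1.6, 1.05, 1.6], s),
        signature("TRO 30.0", [1.1, 1.1, 1.5, 1.2, 1.0], [1.0] * 5, [1.1, 1.1, 1.8, 1.2, 1.0], s),
        # NMDA antagonist: mixed - broad decrease, parieto-occipital theta up
        signature("DIZ 0.25", [0.85, 0.85, 0.85, 0.6, 0.85], [0.85, 1.4, 0.85, 0.6, 0.85],
                  [0.85, 1.4, 0.85, 0.6, 0.85], s),
        # GABA-B mimetic: frontal low-frequency increase, distal beta-HF down
        signature("PHB 100.0", [1.6, 1.6, 1.3, 1.3, 1.2], [1.05, 1.05, 1.05, 1.05, 0.8],
                  [1.05, 1.05, 1.05, 1.05, 0.8], s),
        # H1/5-HT2A blocker: alpha (and with dose beta-LF / frontal) increase
        signature("HXZ 1.0", [1.1, 1.1, 1.3, 1.1, 1.1], [1.1, 1.1, 1.3, 1.1, 1.1],
                  [1.1, 1.1, 1.3, 1.1, 1.1], s),
        signature("HXZ 5.0", [1.15, 1.15, 1.5, 1.5, 1.15], [1.15, 1.15, 1.5, 1.5, 1.15],
                  [1.15, 1.15, 1.5, 1.5, 1.15], s),
        signature("HXZ 20.0", [1.3, 1.3, 1.7, 1.7, 1.3], [1.1, 1.1, 1.35, 1.35, 1.1],
                  [1.1, 1.1, 1.35, 1.35, 1.1], s),
        # benzodiazepine: broadband increase, beta-LF and occipital emphasis
        signature("PHE 0.1", [1.3, 1.3, 1.3, 1.7, 1.3], [1.3, 1.3, 1.3, 1.7, 1.3],
                  [1.5, 1.5, 1.5, 1.9, 1.5], s),
        signature("PHE 1.0", [1.9, 1.0, 1.5, 1.9, 1.5], [1.9, 1.0, 1.5, 1.9, 1.5],
                  [2.1, 1.0, 1.5, 1.9, 1.5], s),
        # alpha-2 agonist: dramatic frontal broadband increase
        signature("DEX 0.005", [2.5] * 5, [1.0, 1.5, 1.5, 1.0, 1.5], [1.5, 1.5, 1.5, 1.0, 1.5], s),
        signature("DEX 0.01", [2.0, 2.0, 2.0, 1.2, 1.5], [2.0, 2.0, 2.0, 1.2, 0.7],
                  [2.0, 2.0, 2.0, 1.2, 0.7], s),
    ]


@dataclass(frozen=True)
class BaselineSpec:
    """Parameters of the quiet-wake baseline signal for one phase."""

    fs: float = 500.0
    duration_s: float = 60.0
    band_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    noise_floor: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        top = max(hi for _, hi in PARTITION_BANDS.values())
        if self.fs <= 2 * top:
            raise ConfigurationError(
                f"fs={self.fs} must exceed twice the top band edge ({top} Hz)"
            )
        if self.duration_s < 5.0:
            raise ConfigurationError(
                f"duration_s={self.duration_s} must be >= the 5-s analysis epoch"
            )
        unknown = set(self.band_amplitudes) - set(BAND_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown band name(s) in band_amplitudes: {sorted(unknown)}")
        if any(v < 0 for v in self.band_amplitudes.values()) or self.noise_floor < 0:
            raise ConfigurationError("band amplitudes and noise_floor must be >= 0")


#: Order of the zero-phase Butterworth used to shape band components.
#: Steeper than the analysis filter so that generated band power stays
#: almost entirely inside its designed rhythm interval.
_SHAPING_ORDER = 8


def _unit_rms_bandnoise(
    rng: np.random.Generator, band: tuple[float, float], fs: float, n: int, pad: int
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, one row per channel, edge-trimmed."""
    total = n + 2 * pad
    noise = rng.standard_normal((len(CHANNELS), total))
    comp = sps.sosfiltfilt(_band_sos(band[0], band[1], fs, _SHAPING_ORDER), noise, axis=-1)
    comp = comp[:, pad : pad + n]
    rms = np.sqrt(np.mean(comp**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return comp / rms


def _pink_floor(rng: np.random.Generator, fs: float, n: int, pad: int) -> np.ndarray:
    """Unit-RMS 1/f broadband noise band-limited to the passband."""
    total = n + 2 * pad
    white = rng.standard_normal((len(CHANNELS), total))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(total, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    y = np.fft.irfft(spec * shaping, n=total, axis=-1)
    y = sps.sosfiltfilt(_band_sos(0.5, 35.0, fs), y, axis=-1)
    y = y[:, pad : pad + n]
    rms = np.sqrt(np.mean(y**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return y / rms


def _render_phase(
    spec: BaselineSpec,
    rng: np.random.Generator,
    gains: np.ndarray,
    power_scale: pd.DataFrame | None,
) -> np.ndarray:
    """Synthesize one phase; ``power_scale`` (regions x bands) multiplies band power."""
    n = int(round(spec.fs * spec.duration_s))
    pad = int(round(spec.fs))  # 1 s of filter warm-up discarded at each end
    out = np.zeros((len(CHANNELS), n))
    for band_name in BAND_ORDER:
        amp = float(spec.band_amplitudes.get(band_name, 0.0))
        if amp <= 0:
            continue
        comp = _unit_rms_bandnoise(rng, PARTITION_BANDS[band_name], spec.fs, n, pad)
        scale = np.full(len(CHANNELS), amp)
        if power_scale is not None:
            for ci, ch in enumerate(CHANNELS):
                scale[ci] *= np.sqrt(power_scale.loc[REGION_OF[ch], band_name])
        out += comp * (scale * gains)[:, None]
    if spec.noise_floor > 0:
        out += _pink_floor(rng, spec.fs, n, pad) * (spec.noise_floor * gains)[:, None]
    return out


def generate_baseline(
    spec: BaselineSpec,
    seed: int | np.random.SeedSequence | None = None,
    *,
    animal_gains: np.ndarray | None = None,
    **meta: str,
) -> EcogRecording:
    """Generate one quiet-wake recording (pre-injection statistics)."""
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    gains = np.ones(len(CHANNELS)) if animal_gains is None else np.asarray(animal_gains, float)
    samples = _render_phase(spec, rng, gains, None)
    return EcogRecording(samples, fs=spec.fs, phase="pre", **meta)


def apply_drug_effect(
    baseline_spec: BaselineSpec,
    sig: DrugSignature,
    record_seed: int,
    *,
    animal_id: str = "",
    record_id: str = "",
) -> tuple[EcogRecording, EcogRecording]:
    """Draw one paired pre/post recording for one administration.

    Both phases share the animal's per-channel gain draws; the post phase
    multiplies each region x band component's power by the signature
    multiplier times a lognormal(0, jitter_sd) record-level draw.
    """
    ss = np.random.SeedSequence(record_seed)
    k_gain, k_pre, k_post, k_jit = ss.spawn(4)
    gains = np.exp(ANIMAL_GAIN_SD * np.random.default_rng(k_gain).standard_normal(len(CHANNELS)))
    meta = dict(animal_id=animal_id, group=sig.class_id, record_id=record_id)
    pre = EcogRecording(
        _render_phase(baseline_spec, np.random.default_rng(k_pre), gains, None),
        fs=baseline_spec.fs,
        phase="pre",
        **meta,
    )
    jitter = np.exp(
        sig.jitter_sd
        * np.random.default_rng(k_jit).standard_normal((len(REGION_ORDER), len(BAND_ORDER)))
    )
    scale = sig.multipliers * pd.DataFrame(
        jitter, index=list(REGION_ORDER), columns=list(BAND_ORDER)
    )
    post = EcogRecording(
        _render_phase(baseline_spec, np.random.default_rng(k_post), gains, scale),
        fs=baseline_spec.fs,
        phase="post",
        **meta,
    )
    return pre, post


@dataclass
class Panel:
    """A labelled collection of paired recordings plus its manifest."""

    pairs: list[tuple[EcogRecording, EcogRecording]]
    manifest: pd.DataFrame  # record_id, animal_id, group, seed


def generate_panel(
    signatures: Sequence[DrugSignature],
    n_per_group: int,
    seed: int,
    baseline: BaselineSpec | None = None,
) -> Panel:
    """Generate ``n_per_group`` paired recordings per signature.

    Per-record integer seeds (< 2^31, unique) are derived from the panel
    seed, so regeneration with the same seed is bit-for-bit identical.
    """
    if n_per_group < 1:
        raise ConfigurationError(f"n_per_group must be >= 1, got {n_per_group}")
    ids = [s.class_id for s in signatures]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ConfigurationError(f"duplicate signature class_id {dup!r}")
    baseline = baseline or BaselineSpec()
    total = len(signatures) * n_per_group
    rng = np.random.default_rng(seed)
    seeds: list[int] = []
    seen: set[int] = set()
    while len(seeds) < total:
        s = int(rng.integers(0, 2**31))
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    pairs = []
    rows = []
    idx = 0
    for sig in signatures:
        for j in range(n_per_group):
            record_id = f"{sig.class_id.replace(' ', '_')}-{j + 1:02d}"
            animal_id = f"A{idx + 1:03d}"
            pre, post = apply_drug_effect(
                baseline, sig, seeds[idx], animal_id=animal_id, record_id=record_id
            )
            pairs.append((pre, post))
            rows.append(
                dict(record_id=record_id, animal_id=animal_id, group=sig.class_id, seed=seeds[idx])
            )
            idx += 1
    return Panel(pairs=pairs, manifest=pd.DataFrame(rows))


def save_panel(panel: Panel, out_dir: str | Path) -> Path:
    """Write one delimited-text file per recording plus a manifest table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    by_id = {row["record_id"]: row for row in panel.manifest.to_dict("records")}
    for pre, post in panel.pairs:
        meta = by_id[pre.record_id]
        for rec in (pre, post):
            fname = f"{rec.record_id}_{rec.phase}.csv"
            write_recording(rec, out_dir / fname)
            rows.append({**meta, "phase": rec.phase, "path": fname})
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False, lineterminator="\n")
    return manifest_path


def load_panel(manifest_path: str | Path) -> Panel:
    """Re-assemble a saved panel; pre/post pairing is explicit in the manifest."""
    from .io import read_recording  # local import to avoid cycle at module load

    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FormatError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    needed = {"record_id", "animal_id", "group", "phase", "path"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"{manifest_path}: manifest missing column(s) {sorted(missing)}")
    pairs = []
    rows = []
    for record_id, sub in df.groupby("record_id", sort=False):
        phases = dict(zip(sub["phase"], sub["path"]))
        if set(phases) != {"pre", "post"}:
            raise FormatError(
                f"{manifest_path}: record {record_id!r} must have exactly one "
                f"'pre' and one 'post' row, got {sorted(phases)}"
            )
        pre = read_recording(manifest_path.parent / phases["pre"])
        post = read_recording(manifest_path.parent / phases["post"])
        pairs.append((pre, post))
        first = sub.iloc[0]
        rows.append(
            dict(
                record_id=record_id,
                animal_id=first["animal_id"],
                group=first["group"],
                seed=int(first["seed"]) if "seed" in sub.columns else -1,
            )
        )
    return Panel(pairs=pairs, manifest=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# panel configuration files


def save_panel_config(
    path: str | Path, baseline: BaselineSpec, signatures: Sequence[DrugSignature]
) -> Path:
    doc = {
        "baseline": {
            "fs": baseline.fs,
            "duration_s": baseline.duration_s,
            "band_amplitudes": dict(baseline.band_amplitudes),
            "noise_floor": baseline.noise_floor,
        },
        "signatures": [
            {
                "class_id": sig.class_id,
                "jitter_sd": sig.jitter_sd,
                "multipliers": {
                    region: [float(v) for v in sig.multipliers.loc[region]]
                    for region in REGION_ORDER
                },
            }
            for sig in signatures
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def load_panel_config(path: str | Path) -> tuple[BaselineSpec, list[DrugSignature]]:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"panel config not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML: {exc}") from None
    if not isinstance(doc, dict) or "signatures" not in doc:
        raise ConfigurationError(f"{path}: panel config must define 'signatures'")
    base = doc.get("baseline", {}) or {}
    baseline = BaselineSpec(
        fs=float(base.get("fs", 500.0)),
        duration_s=float(base.get("duration_s", 60.0)),
        band_amplitudes=dict(base.get("band_amplitudes", DEFAULT_BAND_AMPLITUDES)),
        noise_floor=float(base.get("noise_floor", 5.0)),
    )
    signatures = []
    for entry in doc["signatures"]:
        try:
            mult = entry["multipliers"]
            signatures.append(
                signature(
                    str(entry["class_id"]),
                    mult["frontal"],
                    mult["parietal"],
                    mult["occipital"],
                    float(entry.get("jitter_sd", 0.1)),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"{path}: malformed signature entry: {exc}") from None
    return baseline, signatures
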