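"""Read and write two-channel I/Q recordings as PCM WAV files.

SDR front-ends commonly dump complex baseband as a stereo WAV: the in-phase
component on one channel and the quadrature component on the other.  This
module fixes the convention I = channel 0, Q = channel 1 (the usual SDR
tooling layout; the reverse can be handled downstream by swapping channels)
and keeps capture metadata — demodulation centre frequency, attenuation,
free-text label — in a JSON sidecar next to the WAV rather than in WAV tags,
whose dialects are unreliable.

Integer PCM is scaled by ``2**(bits-1)`` so that the most negative code maps
exactly to -1.0; a 16-bit round trip therefore preserves every sample to
within one quantisation step (2**-15 per component).  Float WAVs are accepted
read-only as a convenience; the writer emits PCM only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import FormatError, RangeError, UnsupportedFormatError

__all__ = ["IQRecording", "read_iq_wav", "write_iq_wav", "sidecar_path"]


@dataclass
class IQRecording:
    """A complex baseband capture.

    Parameters
    ----------
    samples : ndarray of complex
        Dimensionless full-scale samples; components live in [-1, 1).
    sample_rate_hz : float
        WAV header rate, samples per second.
    center_frequency_hz : float
        Demodulation frequency the capture was taken at (informational; e.g.
        63.64 MHz at 1.5 T).
    source_bit_depth : int or None
        Bit depth of the integer PCM source, if known.
    label : str
        Free-text description.
    attenuation_db : float or None
        Front-end attenuation recorded in the sidecar, if any.
    """

    samples: np.ndarray
    sample_rate_hz: float
    center_frequency_hz: float = 0.0
    source_bit_depth: int | None = None
    label: str = ""
    attenuation_db: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D complex sequence")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def time_axis(self) -> np.ndarray:
        """Sample times in seconds from the start of the capture."""
        return np.arange(self.samples.size) / self.sample_rate_hz


def sidecar_path(wav_path: str | Path) -> Path:
    """Path of the metadata sidecar belonging to ``wav_path``.

    ``capture.wav`` maps to ``capture.meta.json``.
    """
    p = Path(wav_path)
    return p.with_name(p.stem + ".meta.json")


def read_iq_wav(path: str | Path, sidecar: str | Path | None = None) -> IQRecording:
    """Read a 2-channel PCM (or float) WAV into an :class:`IQRecording`.

    Channel 0 is taken as I, channel 1 as Q.  Integer PCM is scaled by
    ``1 / 2**(bits-1)``; 8-bit WAV (stored unsigned per the RIFF convention)
    is re-centred about zero first.  Metadata is merged from the sidecar JSON
    when present (the default sidecar next to the WAV is used when the
    argument is omitted).

    Raises
    ------
    FormatError
        Mono or >2-channel file.
    UnsupportedFormatError
        Compressed / non-PCM encodings.
    FileNotFoundError
        Missing WAV file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such WAV file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise UnsupportedFormatError(f"unsupported WAV encoding in {path}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 2:
        nch = 1 if data.ndim == 1 else data.shape[1]
        raise FormatError(
            f"{path} has {nch} channel(s); an I/Q recording needs exactly 2"
        )

    bits: int | None
    if data.dtype == np.int16:
        bits = 16
        scaled = data.astype(np.float64) / 2**15
    elif data.dtype == np.uint8:
        bits = 8
        scaled = (data.astype(np.float64) - 128.0) / 2**7
    elif data.dtype == np.int32:
        bits = 32
        scaled = data.astype(np.float64) / 2**31
    elif data.dtype in (np.float32, np.float64):
        bits = None
        scaled = data.astype(np.float64)
    else:  # pragma: no cover - wavfile restricts dtypes already
        raise UnsupportedFormatError(f"unsupported WAV sample type {data.dtype}")

    samples = scaled[:, 0] + 1j * scaled[:, 1]

    meta: dict = {}
    sc = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())

    return IQRecording(
        samples=samples,
        sample_rate_hz=float(rate),
        center_frequency_hz=float(meta.get("center_frequency_hz", 0.0)),
        source_bit_depth=bits,
        label=str(meta.get("label", "")),
        attenuation_db=meta.get("attenuation_db"),
    )


def write_iq_wav(
    rec: IQRecording,
    path: str | Path,
    bit_depth: int = 16,
    clip: bool = True,
) -> Path:
    """Write an :class:`IQRecording` as 2-channel integer PCM WAV + sidecar.

    Channel 0 receives the real part, channel 1 the imaginary part, each
    scaled by ``2**(bit_depth-1)`` and clipped to the integer range (the
    positive rail is one step short of +1.0, so +1.0 saturates to full
    positive code).

    Parameters
    ----------
    bit_depth : {8, 16}
        8-bit output is stored unsigned (offset 128) per the RIFF convention.
    clip : bool
        With ``clip=False``, out-of-range samples raise :class:`RangeError`
        instead of saturating.

    Returns
    -------
    Path of the written WAV; the sidecar is written beside it.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    iq = np.column_stack([rec.samples.real, rec.samples.imag])
    if not clip and np.any(np.abs(iq) > 1.0):
        raise RangeError("samples exceed [-1, 1] and clipping is disabled")

    full = 2 ** (bit_depth - 1)
    codes = np.round(iq * full)
    codes = np.clip(codes, -full, full - 1)
    if bit_depth == 16:
        payload = codes.astype(np.int16)
    else:
        payload = (codes + 128).astype(np.uint8)
    wavfile.write(str(path), int(round(rec.sample_rate_hz)), payload)

    meta = {
        "center_frequency_hz": rec.center_frequency_hz,
        "label": rec.label,
    }
    if rec.attenuation_db is not None:
        meta["attenuation_db"] = rec.attenuation_db
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path
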