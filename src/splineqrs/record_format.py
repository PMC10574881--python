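"""Reader/writer for the monitor's binary record layout.

A recording is a directory named ``<subject>_<YYYYMMDD>_<HHMMSS>``.  Inside,
``Record0000`` holds the metadata (subject, sampling rate, device-on
timestamps) as UTF-8 key-value lines, and ``Record0001`` ... ``Record9999``
hold the sample stream as 15-byte packets: 5 bytes per channel (DI, aVF,
V2), each channel a 3-byte big-endian two's-complement ADC code followed by
a 2-byte big-endian heart-rate word.  The HR word is unsigned bpm x 10
fixed point, 0 meaning "no beat yet".

The module also provides the front end's code/voltage arithmetic: with
reference voltage ``V_REF`` and programmable gain ``G`` the full-scale input
range is ``±V_REF/G`` and one LSB of the ``n``-bit converter is
``(2 V_REF / G) / (2**n - 1)`` (286.10 nV at V_REF = 2.4 V, unity gain,
n = 24).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from .containers import DEFAULT_LEADS, EcgRecord

__all__ = [
    "RecordHeader",
    "SamplePacket",
    "DeviceSpec",
    "PACKET_BYTES",
    "PACKETS_PER_FILE",
    "encode_packet",
    "decode_packet",
    "adc_code_to_volts",
    "volts_to_adc_code",
    "storage_requirement",
    "directory_name",
    "write_record",
    "read_record",
    "hr_bpm_to_word",
    "hr_word_to_bpm",
]

PACKET_BYTES = 15
#: Packets per RecordNNNN data file (~65 s at 1000 Hz).
PACKETS_PER_FILE = 2**16
_N_CHANNELS = 3
_CODE_MIN, _CODE_MAX = -(2**23), 2**23 - 1
_ALLOWED_RATES = (250, 500, 1000)
_ALLOWED_GAINS = (1, 2, 3, 4, 6, 8, 12)


class RecordFormatError(ValueError):
    """Raised for malformed packets, files or record directories."""


@dataclass(frozen=True)
class DeviceSpec:
    """ADC front-end parameters: reference voltage, gain and bit depth."""

    v_ref: float = 2.4
    gain: int = 1
    n_bits: int = 24

    def __post_init__(self) -> None:
        if self.v_ref <= 0:
            raise ValueError("v_ref must be positive")
        if self.gain not in _ALLOWED_GAINS:
            raise ValueError(f"gain must be one of {_ALLOWED_GAINS}, got {self.gain}")

    @property
    def lsb_volts(self) -> float:
        """Input voltage step of one code: ``(2 v_ref / gain) / (2^n - 1)``."""
        return (2.0 * self.v_ref / self.gain) / (2**self.n_bits - 1)


@dataclass
class RecordHeader:
    """Metadata stored in ``Record0000``."""

    subject_name: str
    age: int
    sex: str
    sampling_rate_hz: int
    start_on_time: str = ""
    end_on_time: str = ""
    gain: int = 1

    def __post_init__(self) -> None:
        if self.sampling_rate_hz not in _ALLOWED_RATES:
            raise ValueError(
                f"sampling_rate_hz must be one of {_ALLOWED_RATES}, "
                f"got {self.sampling_rate_hz}"
            )


@dataclass(frozen=True)
class SamplePacket:
    """One 15-byte storage unit: 3 channels of (24-bit code, 16-bit HR word)."""

    adc_codes: tuple[int, int, int]
    hr_words: tuple[int, int, int] = (0, 0, 0)


def encode_packet(packet: SamplePacket) -> bytes:
    """Serialize a packet channel-major, big-endian, to exactly 15 bytes."""
    out = bytearray()
    for code, hr in zip(packet.adc_codes, packet.hr_words, strict=True):
        if not (_CODE_MIN <= code <= _CODE_MAX):
            raise RecordFormatError(f"ADC code {code} outside 24-bit range")
        if not (0 <= hr <= 0xFFFF):
            raise RecordFormatError(f"HR word {hr} outside 16-bit range")
        out += int(code).to_bytes(3, "big", signed=True)
        out += int(hr).to_bytes(2, "big")
    return bytes(out)


def decode_packet(block: bytes) -> SamplePacket:
    """Exact inverse of :func:`encode_packet`."""
    if len(block) != PACKET_BYTES:
        raise RecordFormatError(f"packet must be {PACKET_BYTES} bytes, got {len(block)}")
    codes, hrs = [], []
    for ch in range(_N_CHANNELS):
        off = 5 * ch
        codes.append(int.from_bytes(block[off : off + 3], "big", signed=True))
        hrs.append(int.from_bytes(block[off + 3 : off + 5], "big"))
    return SamplePacket(adc_codes=tuple(codes), hr_words=tuple(hrs))


def adc_code_to_volts(code: int | np.ndarray, spec: DeviceSpec = DeviceSpec()) -> float | np.ndarray:
    """Voltage of an ADC code: ``code x (2 v_ref / gain) / (2^n - 1)``."""
    return code * spec.lsb_volts


def volts_to_adc_code(volts: float | np.ndarray, spec: DeviceSpec = DeviceSpec()) -> np.ndarray:
    """Quantize voltages to the nearest in-range ADC code."""
    codes = np.rint(np.asarray(volts, dtype=float) / spec.lsb_volts)
    return np.clip(codes, _CODE_MIN, _CODE_MAX).astype(np.int64)


def storage_requirement(sampling_rate_hz: float, duration_s: float) -> tuple[float, float]:
    """Minimum storage for a recording: ``15 bytes x Fm x t``.

    Returns ``(bytes, GiB)``; 24 h at 1000 Hz needs 1.296e9 bytes = 1.21 GiB.
    """
    if sampling_rate_hz < 0 or duration_s < 0:
        raise ValueError("sampling rate and duration must be non-negative")
    nbytes = PACKET_BYTES * sampling_rate_hz * duration_s
    return nbytes, nbytes / 2**30


def directory_name(subject: str, start: datetime) -> str:
    """Deterministic record-directory name ``<subject>_<YYYYMMDD>_<HHMMSS>``."""
    sanitized = re.sub(r"[^A-Za-z0-9_-]+", "-", subject.strip())
    if not sanitized:
        raise ValueError("subject name must be non-empty")
    return f"{sanitized}_{start:%Y%m%d_%H%M%S}"


def hr_bpm_to_word(hr_bpm: float | None) -> int:
    """Encode bpm as the unsigned bpm x 10 fixed-point HR word (0 = none)."""
    if hr_bpm is None:
        return 0
    return int(np.clip(round(hr_bpm * 10), 0, 0xFFFF))


def hr_word_to_bpm(word: int) -> float | None:
    """Decode the HR word; 0 means no heart rate yet."""
    return None if word == 0 else word / 10.0


def _header_path(directory: Path) -> Path:
    return directory / "Record0000"


def write_record(
    record: EcgRecord,
    hr_words: np.ndarray | None,
    header: RecordHeader,
    path: str | Path,
    spec: DeviceSpec | None = None,
) -> Path:
    """Write a 3-lead record directory.

    ``hr_words`` is an ``(n_samples, 3)`` array of 16-bit HR words aligned
    sample-wise with the record (the most recent heart rate of each lead at
    that sample), or ``None`` for all-zero words.  If the record carries raw
    ``adc_codes`` they are stored verbatim; otherwise the voltage samples are
    quantized with ``spec``.
    """
    if record.n_leads != _N_CHANNELS:
        raise ValueError(f"record must have exactly {_N_CHANNELS} leads")
    spec = spec if spec is not None else DeviceSpec(gain=header.gain)
    if record.adc_codes is not None:
        codes = np.asarray(record.adc_codes, dtype=np.int64)
    else:
        codes = volts_to_adc_code(record.samples, spec)
    n = codes.shape[0]
    if hr_words is None:
        hr_words = np.zeros((n, _N_CHANNELS), dtype=np.int64)
    hr_words = np.asarray(hr_words, dtype=np.int64)
    if hr_words.shape != codes.shape:
        raise ValueError("hr_words must align sample-wise with the record")

    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [
        f"subject_name={header.subject_name}",
        f"age={header.age}",
        f"sex={header.sex}",
        f"sampling_rate_hz={header.sampling_rate_hz}",
        f"start_on_time={header.start_on_time}",
        f"end_on_time={header.end_on_time}",
        f"gain={header.gain}",
    ]
    _header_path(directory).write_text("\n".join(lines) + "\n", encoding="utf-8")

    if codes.size and (codes.min() < _CODE_MIN or codes.max() > _CODE_MAX):
        raise RecordFormatError("ADC code outside 24-bit range")
    if hr_words.size and (hr_words.min() < 0 or hr_words.max() > 0xFFFF):
        raise RecordFormatError("HR word outside 16-bit range")
    # vectorized packet serialization: (n, 3 channels, 5 bytes) big-endian
    u = np.where(codes < 0, codes + 2**24, codes).astype(np.uint32)
    blob = np.empty((n, _N_CHANNELS, 5), dtype=np.uint8)
    blob[:, :, 0] = (u >> 16) & 0xFF
    blob[:, :, 1] = (u >> 8) & 0xFF
    blob[:, :, 2] = u & 0xFF
    blob[:, :, 3] = (hr_words >> 8) & 0xFF
    blob[:, :, 4] = hr_words & 0xFF
    flat = blob.reshape(n, PACKET_BYTES)

    n_files = max(1, math.ceil(n / PACKETS_PER_FILE))
    if n_files > 9999:
        raise RecordFormatError("record exceeds the Record0001..Record9999 naming range")
    for i in range(n_files):
        part = flat[i * PACKETS_PER_FILE : (i + 1) * PACKETS_PER_FILE]
        (directory / f"Record{i + 1:04d}").write_bytes(part.tobytes())
    return directory


def read_record(
    path: str | Path, spec: DeviceSpec | None = None
) -> tuple[EcgRecord, np.ndarray, RecordHeader]:
    """Read a record directory back into ``(EcgRecord, hr_words, header)``.

    ``read_record`` after :func:`write_record` is the identity on ADC codes,
    HR words and header fields.
    """
    directory = Path(path)
    hp = _header_path(directory)
    if not hp.is_file():
        raise RecordFormatError(f"missing Record0000 metadata file in {directory}")
    fields: dict[str, str] = {}
    for line in hp.read_text(encoding="utf-8").splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
    header = RecordHeader(
        subject_name=fields.get("subject_name", ""),
        age=int(fields.get("age", 0)),
        sex=fields.get("sex", ""),
        sampling_rate_hz=int(fields["sampling_rate_hz"]),
        start_on_time=fields.get("start_on_time", ""),
        end_on_time=fields.get("end_on_time", ""),
        gain=int(fields.get("gain", 1)),
    )
    spec = spec if spec is not None else DeviceSpec(gain=header.gain)

    data_files = sorted(
        p for p in directory.iterdir() if re.fullmatch(r"Record\d{4}", p.name) and p.name != "Record0000"
    )
    codes_rows, hr_rows = [], []
    for p in data_files:
        blob = p.read_bytes()
        if len(blob) % PACKET_BYTES:
            raise RecordFormatError(f"{p.name} size {len(blob)} is not a multiple of {PACKET_BYTES}")
        arr = np.frombuffer(blob, dtype=np.uint8).reshape(-1, PACKET_BYTES)
        by_ch = arr.reshape(-1, _N_CHANNELS, 5)
        code = (
            (by_ch[:, :, 0].astype(np.int64) << 16)
            | (by_ch[:, :, 1].astype(np.int64) << 8)
            | by_ch[:, :, 2].astype(np.int64)
        )
        code = np.where(code >= 2**23, code - 2**24, code)
        hr = (by_ch[:, :, 3].astype(np.int64) << 8) | by_ch[:, :, 4].astype(np.int64)
        codes_rows.append(code)
        hr_rows.append(hr)
    if codes_rows:
        codes = np.concatenate(codes_rows)
        hr_words = np.concatenate(hr_rows)
    else:
        codes = np.empty((0, _N_CHANNELS), dtype=np.int64)
        hr_words = np.empty((0, _N_CHANNELS), dtype=np.int64)

    record = EcgRecord(
        samples=codes * spec.lsb_volts,
        sampling_rate_hz=float(header.sampling_rate_hz),
        leads=DEFAULT_LEADS,
        adc_codes=codes,
    )
    return record, hr_words, header
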