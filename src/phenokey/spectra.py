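"""Spectrum data model, peak-matching primitives and readers/writers.

Supported formats:

* ``msp`` and ``mgf`` -- standard spectral-library formats (via matchms);
* ``tsv`` -- a fixture dialect transcribing literature tables: UTF-8 TSV,
  one row per compound with a fragment list typeset as
  ``"m/z (relative abundance %); ..."``.

All readers return spectra with abundances normalized to the base peak
(= 100%); zero-abundance peaks are dropped with a warning, and exact
duplicate fragment m/z values within one record keep the first occurrence
(transcription artifacts occur in printed tables).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FragmentPeak",
    "MsMsSpectrum",
    "BasePeak",
    "Tolerance",
    "base_peak",
    "find_peak",
    "read_spectra",
    "write_spectra",
]


@dataclass(frozen=True)
class FragmentPeak:
    """One MS/MS peak: m/z (Da) and relative abundance (% of base peak)."""

    mz: float
    abundance: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if not (0 <= self.abundance <= 100 + 1e-9):
            raise ValueError(
                f"relative abundance must be in (0, 100], got {self.abundance}"
            )


@dataclass(frozen=True)
class MsMsSpectrum:
    """A negative-mode MS/MS spectrum of a deprotonated molecule.

    ``precursor_mz`` is the [M-H]- value; ``dimer_mz`` the optional
    proton-bound [2M-H]- observed in full scan.  ``metadata`` carries any
    extra fields a reader found (compound name, ground truth, ...).
    """

    identifier: str
    precursor_mz: float
    peaks: tuple[FragmentPeak, ...]
    retention_time: float | None = None
    formula: str | None = None
    dimer_mz: float | None = None
    dimer_abundance: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.retention_time is not None and self.retention_time < 0:
            raise ValueError("retention time must be >= 0")
        if len(self.peaks) < 1:
            raise ValueError(f"spectrum {self.identifier!r} has no fragment peaks")
        limit = self.precursor_mz + 0.05  # matching slack above the precursor
        for p in self.peaks:
            if p.mz > limit:
                raise ValueError(
                    f"spectrum {self.identifier!r}: fragment {p.mz} above precursor "
                    f"{self.precursor_mz}"
                )

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def abundance_array(self) -> np.ndarray:
        return np.array([p.abundance for p in self.peaks])

    def normalized(self) -> "MsMsSpectrum":
        """Rescale abundances so the base peak is exactly 100 (idempotent)."""
        top = max(p.abundance for p in self.peaks)
        if top == 100.0:
            return self
        scale = 100.0 / top
        return replace(
            self,
            peaks=tuple(
                FragmentPeak(p.mz, p.abundance * scale) for p in self.peaks
            ),
        )


class BasePeak(NamedTuple):
    peak: FragmentPeak
    tie: bool


def base_peak(spectrum: MsMsSpectrum) -> BasePeak:
    """The most abundant fragment; ties go to the lower m/z with a flag."""
    top = max(p.abundance for p in spectrum.peaks)
    winners = [p for p in spectrum.peaks if p.abundance == top]
    winners.sort(key=lambda p: p.mz)
    return BasePeak(peak=winners[0], tie=len(winners) > 1)


@dataclass(frozen=True)
class Tolerance:
    """An MS2 match tolerance: absolute (mDa) or relative (ppm).

    The default is absolute 10 mDa: printed MS2 axes commonly sit a few ppm
    below theory, and an absolute window keeps low-m/z diagnostic ions
    (85-197) matchable with one setting.
    """

    mda: float | None = 10.0
    ppm: float | None = None

    def __post_init__(self):
        if (self.mda is None) == (self.ppm is None):
            raise ValueError("specify exactly one of mda= or ppm=")
        value = self.mda if self.mda is not None else self.ppm
        if value <= 0:
            raise ValueError("tolerance must be positive")

    def window_da(self, target_mz: float) -> float:
        if self.mda is not None:
            return self.mda * 1e-3
        return target_mz * self.ppm * 1e-6


def find_peak(
    spectrum: MsMsSpectrum,
    target_mz: float,
    tolerance: Tolerance = Tolerance(),
) -> FragmentPeak | None:
    """Nearest in-tolerance peak to ``target_mz``, or None."""
    window = tolerance.window_da(target_mz)
    best, best_err = None, window
    for p in spectrum.peaks:
        err = abs(p.mz - target_mz)
        if err <= best_err:
            best, best_err = p, err
    return best


# ---------------------------------------------------------------------------
# readers / writers

_FRAGMENT_RE = re.compile(r"([\d.]+)\s*\(([\d.]+)\)")

FIXTURE_COLUMNS = ("id", "precursor_mz", "fragments")


def _parse_fragment_list(text: str, where: str) -> list[FragmentPeak]:
    peaks: list[FragmentPeak] = []
    seen: set[str] = set()
    consumed = 0
    for m in _FRAGMENT_RE.finditer(text):
        mz_text, ab_text = m.group(1), m.group(2)
        if mz_text in seen:
            warnings.warn(
                f"{where}: duplicate fragment m/z {mz_text} -- keeping first occurrence"
            )
            consumed += 1
            continue
        seen.add(mz_text)
        ab = float(ab_text)
        if ab == 0:
            warnings.warn(f"{where}: dropping zero-abundance peak at {mz_text}")
            consumed += 1
            continue
        peaks.append(FragmentPeak(float(mz_text), ab))
        consumed += 1
    if consumed == 0 and text.strip():
        raise ValueError(f"{where}: unparseable fragment list {text!r}")
    return peaks


def _read_fixture_tsv(path: Path) -> list[MsMsSpectrum]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in FIXTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fixture TSV lacks required column(s) {missing}")
    spectra = []
    for i, row in df.iterrows():
        where = f"{path.name} line {i + 2}"
        try:
            peaks = _parse_fragment_list(row["fragments"], where)
            if not peaks:
                raise ValueError("no usable fragment peaks")
            known = {"id", "precursor_mz", "fragments", "rt_min", "formula",
                     "dimer_mz", "dimer_abundance"}
            meta = {
                k: row[k] for k in df.columns
                if k not in known and pd.notna(row[k])
            }

            def _opt(col):
                return (
                    float(row[col])
                    if col in df.columns and pd.notna(row[col])
                    else None
                )

            spec = MsMsSpectrum(
                identifier=str(row["id"]),
                precursor_mz=float(row["precursor_mz"]),
                peaks=tuple(peaks),
                retention_time=_opt("rt_min"),
                formula=row["formula"] if "formula" in df.columns and pd.notna(row["formula"]) else None,
                dimer_mz=_opt("dimer_mz"),
                dimer_abundance=_opt("dimer_abundance"),
                metadata=meta,
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{where}, field error: {exc}") from exc
        spectra.append(spec.normalized())
    return spectra


def _from_matchms(ms) -> MsMsSpectrum:
    meta = dict(ms.metadata)
    meta.pop("num_peaks", None)
    precursor = meta.pop("precursor_mz", None)
    if precursor is None:
        raise ValueError("record lacks a precursor m/z")
    peaks = [
        FragmentPeak(float(mz), float(ab))
        for mz, ab in zip(ms.peaks.mz, ms.peaks.intensities)
        if float(ab) > 0
    ]
    if len(peaks) < len(ms.peaks.mz):
        warnings.warn("dropping zero-abundance peak(s) on load")
    rt = meta.pop("retention_time", None)
    spec = MsMsSpectrum(
        identifier=str(meta.pop("id", meta.pop("compound_name", "unknown"))),
        precursor_mz=float(precursor),
        peaks=tuple(peaks),
        retention_time=float(rt) if rt is not None else None,
        formula=meta.pop("formula", None),
        dimer_mz=float(meta.pop("dimer_mz")) if "dimer_mz" in meta else None,
        dimer_abundance=(
            float(meta.pop("dimer_abundance")) if "dimer_abundance" in meta else None
        ),
        metadata=meta,
    )
    return spec.normalized()


def _to_matchms(spectrum: MsMsSpectrum):
    from matchms import Spectrum as MatchmsSpectrum

    meta = {
        "id": spectrum.identifier,
        "precursor_mz": spectrum.precursor_mz,
        **spectrum.metadata,
    }
    if spectrum.retention_time is not None:
        meta["retention_time"] = spectrum.retention_time
    if spectrum.formula is not None:
        meta["formula"] = spectrum.formula
    if spectrum.dimer_mz is not None:
        meta["dimer_mz"] = spectrum.dimer_mz
    if spectrum.dimer_abundance is not None:
        meta["dimer_abundance"] = spectrum.dimer_abundance
    order = np.argsort(spectrum.mz_array)
    return MatchmsSpectrum(
        mz=spectrum.mz_array[order],
        intensities=spectrum.abundance_array[order],
        metadata={k: v for k, v in meta.items() if v is not None},
        metadata_harmonization=False,
    )


def read_spectra(path: str | Path, format: str | None = None) -> list[MsMsSpectrum]:
    """Read spectra from an MSP, MGF or fixture-TSV file.

    ``format`` defaults to the file extension.  An empty file yields an
    empty list with a warning.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not path.read_text(encoding="utf-8").strip():
        warnings.warn(f"{path}: empty input file")
        return []
    if fmt == "tsv":
        return _read_fixture_tsv(path)
    if fmt == "msp":
        from matchms.importing import load_from_msp

        records = load_from_msp(str(path), metadata_harmonization=False)
    elif fmt == "mgf":
        from matchms.importing import load_from_mgf

        records = load_from_mgf(str(path), metadata_harmonization=False)
    else:
        raise ValueError(f"unknown spectra format {fmt!r} (use msp, mgf or tsv)")
    return [_from_matchms(r) for r in records if r is not None]


def write_spectra(
    path: str | Path, spectra: Iterable[MsMsSpectrum], format: str | None = None
) -> None:
    """Write spectra to MSP, MGF or the fixture-TSV dialect."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    spectra = list(spectra)
    if fmt == "tsv":
        rows = []
        for s in spectra:
            rows.append(
                {
                    "id": s.identifier,
                    "precursor_mz": f"{s.precursor_mz:.4f}",
                    "rt_min": "" if s.retention_time is None else s.retention_time,
                    "formula": s.formula or "",
                    "dimer_mz": "" if s.dimer_mz is None else f"{s.dimer_mz:.4f}",
                    "dimer_abundance": (
                        "" if s.dimer_abundance is None else s.dimer_abundance
                    ),
                    "fragments": "; ".join(
                        f"{p.mz:.4f} ({p.abundance:.1f})" for p in s.peaks
                    ),
                    **{k: v for k, v in s.metadata.items()},
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return
    if fmt == "msp":
        from matchms.exporting import save_as_msp

        save_as_msp([_to_matchms(s) for s in spectra], str(path), mode="w")
    elif fmt == "mgf":
        from matchms.exporting import save_as_mgf

        save_as_mgf([_to_matchms(s) for s in spectra], str(path), file_mode="w")
    else:
        raise ValueError(f"unknown spectra format {fmt!r} (use msp, mgf or tsv)")
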