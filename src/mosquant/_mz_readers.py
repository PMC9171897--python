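"""Minimal MS1-only readers for centroided mzML and mzXML documents.

Supports 32/64-bit float binary arrays, uncompressed or zlib-compressed,
minute or second retention-time units; everything else a full-featured
reader would handle (ion mobility arrays, numpress, chromatograms) is out
of scope. Profile-mode input is rejected: the extraction stage assumes
centroided peaks.
"""

from __future__ import annotations

import base64
import re
import zlib

import numpy as np
from lxml import etree

__all__ = ["read_mzml", "read_mzxml"]

_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _localname(el) -> str:
    return etree.QName(el).localname


def _decode_binary(data: str, dtype: str, compressed: bool) -> np.ndarray:
    raw = base64.b64decode(data)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str) -> tuple[list[float], list[np.ndarray], list[np.ndarray]]:
    """Retention times (min), m/z arrays and intensity arrays of MS1 scans."""
    rts: list[float] = []
    mzs: list[np.ndarray] = []
    ints: list[np.ndarray] = []
    for _, spec in etree.iterparse(str(path), tag="{*}spectrum"):
        params = {
            p.get("accession"): p
            for p in spec.iter("{*}cvParam")
        }
        level = params.get(_ACC_MS_LEVEL)
        if level is None or int(level.get("value")) != 1:
            spec.clear(keep_tail=True)
            continue
        if _ACC_PROFILE in params:
            raise ValueError("profile spectrum found; centroided MS1 input required")
        scan_start = params.get(_ACC_SCAN_START)
        if scan_start is None:
            raise ValueError(f"spectrum {spec.get('id')!r} lacks a scan start time")
        rt = float(scan_start.get("value"))
        if scan_start.get("unitName", "minute").startswith("second"):
            rt /= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter("{*}binaryDataArray"):
            acc = {p.get("accession") for p in bda.iter("{*}cvParam")}
            dtype = "<f4" if _ACC_F32 in acc else "<f8"
            binary = bda.find("{*}binary")
            data = _decode_binary(binary.text or "", dtype, _ACC_ZLIB in acc)
            if _ACC_MZ_ARRAY in acc:
                arrays["mz"] = data
            elif _ACC_INT_ARRAY in acc:
                arrays["intensity"] = data
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"spectrum {spec.get('id')!r} lacks m/z or intensity array")
        rts.append(rt)
        mzs.append(arrays["mz"])
        ints.append(arrays["intensity"])
        spec.clear(keep_tail=True)
    return rts, mzs, ints


_ISO_DURATION = re.compile(r"^PT(?:(\d+(?:\.\d+)?)M)?(?:(\d+(?:\.\d+)?)S)?$")


def _parse_mzxml_rt(value: str) -> float:
    """mzXML retentionTime is an xs:duration like 'PT123.4S'; minutes out."""
    m = _ISO_DURATION.match(value.strip())
    if not m:
        raise ValueError(f"unparseable retentionTime: {value!r}")
    minutes = float(m.group(1) or 0.0)
    seconds = float(m.group(2) or 0.0)
    return minutes + seconds / 60.0


def read_mzxml(path: str) -> tuple[list[float], list[np.ndarray], list[np.ndarray]]:
    rts: list[float] = []
    mzs: list[np.ndarray] = []
    ints: list[np.ndarray] = []
    for _, scan in etree.iterparse(str(path), tag="{*}scan"):
        if int(scan.get("msLevel", "0")) != 1:
            scan.clear(keep_tail=True)
            continue
        if scan.get("centroided", "1") in ("0", "false"):
            raise ValueError("profile scan found; centroided MS1 input required")
        rt = _parse_mzxml_rt(scan.get("retentionTime", "PT0S"))
        peaks = scan.find("{*}peaks")
        if peaks is None:
            raise ValueError(f"scan {scan.get('num')!r} lacks a peaks element")
        prec = peaks.get("precision", "32")
        dtype = ">f8" if prec == "64" else ">f4"  # network byte order
        raw = base64.b64decode(peaks.text or "")
        if peaks.get("compressionType", "none") == "zlib":
            raw = zlib.decompress(raw)
        flat = np.frombuffer(raw, dtype=dtype).astype(float)
        rts.append(rt)
        mzs.append(flat[0::2])
        ints.append(flat[1::2])
        scan.clear(keep_tail=True)
    return rts, mzs, ints
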