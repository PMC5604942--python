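"""Serializing fingerprints to QR-codable payloads and back.

A fingerprint is flattened to a fixed-width, index-free string: one
two-character token per panel marker, in panel order, alleles within a
token in lexicographic order, missing calls as ``--``.  For the bundled
80-marker panel the payload is 160 characters over {A,C,G,T,D,I,-}.  The
payload carries no header: the panel identity is implicit, which is a
known interoperability limitation of the bare-string design.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotypes import ALLELE_ALPHABET, MISSING_CHAR, Genotype
from .genotype_io import Fingerprint
from .panel import Panel
from .qr import decode_png, encode_to_png

__all__ = [
    "QRPayload",
    "PayloadError",
    "serialize",
    "deserialize",
    "encode_qr",
    "decode_qr",
]

_PAYLOAD_ALPHABET = ALLELE_ALPHABET | {MISSING_CHAR}


class PayloadError(ValueError):
    """A payload string violates the fingerprint-payload contract."""


@dataclass(frozen=True)
class QRPayload:
    """A serialized fingerprint: 2 characters per marker, panel order."""

    text: str

    def __post_init__(self):
        if len(self.text) % 2:
            raise PayloadError(f"payload length {len(self.text)} is odd")
        for offset, ch in enumerate(self.text):
            if ch not in _PAYLOAD_ALPHABET:
                raise PayloadError(f"illegal payload character {ch!r} at offset {offset}")

    @property
    def n_markers(self) -> int:
        return len(self.text) // 2

    def __str__(self) -> str:
        return self.text


def serialize(fp: Fingerprint) -> QRPayload:
    """Flatten a fingerprint to its canonical index-free payload string."""
    return QRPayload("".join(g.canonical_token for g in fp))


def deserialize(payload, panel: Panel) -> Fingerprint:
    """Rebuild a fingerprint from a payload, validated against the panel size.

    ``payload`` may be a :class:`QRPayload` or a raw string (as returned by
    :func:`decode_qr`); strings are validated here.
    """
    if not isinstance(payload, QRPayload):
        payload = QRPayload(payload)
    expected = 2 * len(panel)
    if len(payload.text) != expected:
        raise PayloadError(
            f"payload length {len(payload.text)} does not match panel "
            f"{panel.name!r} (expected {expected})"
        )
    genotypes = [
        Genotype.from_token(payload.text[i : i + 2])
        for i in range(0, len(payload.text), 2)
    ]
    return Fingerprint(panel_name=panel.name, genotypes=genotypes)


def encode_qr(payload, out_path, ec_level: str = "M", scale: int = 8) -> None:
    """Render a payload as a QR PNG whose decoded text equals the payload."""
    if not isinstance(payload, QRPayload):
        payload = QRPayload(payload)
    encode_to_png(payload.text, out_path, ec_level=ec_level, scale=scale)


def decode_qr(image_path) -> str:
    """Decode a QR image back to its raw text payload.

    Validation of the payload alphabet and length is deferred to
    :func:`deserialize`, so a QR symbol holding arbitrary non-genotype text
    is returned verbatim.
    """
    return decode_png(image_path)
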