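"""Registration, substitution-cipher tokens, and login verification.

A registering patient supplies their identity fields; the patient id and
hospital id are concatenated into a single *combined text* and encrypted
with a keyed cyclic-shift (Caesar) substitution cipher.  The resulting
token acts as a third login credential alongside username and password:
verification succeeds only when username, password, and presented token all
match the stored record.

The cipher shifts letters A-Z/a-z cyclically mod 26 (case preserved) and
digits mod 10; every other character passes through unchanged, so the map
is a bijection on the extended alphabet for every shift and shift
composition adds mod 26.  Passwords are stored salted-and-hashed, never in
the clear.
"""

from __future__ import annotations

import hashlib
import secrets
from dataclasses import dataclass
from pathlib import Path

from .errors import RegistrationError, ValidationError

__all__ = [
    "PatientDetails",
    "CredentialRecord",
    "AuthDecision",
    "CredentialStore",
    "combine_ids",
    "substitution_encrypt",
    "substitution_decrypt",
    "register_patient",
    "verify_login",
]

DEFAULT_SHIFT = 3


@dataclass(frozen=True)
class PatientDetails:
    """Identity fields captured at registration."""

    username: str
    patient_name: str
    sex: str
    age: str
    address: str
    password: str
    patient_id: str
    hospital_id: str
    doctor_name: str

    def __post_init__(self) -> None:
        if not self.patient_id or not self.hospital_id:
            raise ValidationError("patient_id and hospital_id must be nonempty")
        if not self.username:
            raise ValidationError("username must be nonempty")


@dataclass(frozen=True)
class CredentialRecord:
    """A stored registration: details, combined text, cipher token, shift."""

    details: PatientDetails
    combined_text: str
    cipher_token: str
    shift_key: int
    password_salt: str
    password_hash: str


@dataclass(frozen=True)
class AuthDecision:
    status: str  # "authorized" | "unauthorized"
    reason: str = ""

    @property
    def authorized(self) -> bool:
        return self.status == "authorized"


def combine_ids(user_id: str, hospital_id: str) -> str:
    """Merge user id and hospital id into one text by concatenation."""
    if not user_id or not hospital_id:
        raise ValidationError("user_id and hospital_id must be nonempty")
    return user_id + hospital_id


def substitution_encrypt(plaintext: str, shift: int) -> str:
    """Cyclic-shift cipher: letters mod 26 (case kept), digits mod 10."""
    shift %= 26
    out: list[str] = []
    for ch in plaintext:
        if "A" <= ch <= "Z":
            out.append(chr((ord(ch) - 65 + shift) % 26 + 65))
        elif "a" <= ch <= "z":
            out.append(chr((ord(ch) - 97 + shift) % 26 + 97))
        elif "0" <= ch <= "9":
            out.append(chr((ord(ch) - 48 + shift) % 10 + 48))
        else:
            out.append(ch)
    return "".join(out)


def substitution_decrypt(ciphertext: str, shift: int) -> str:
    """Inverse of :func:`substitution_encrypt`.

    Digits shift mod 10 while letters shift mod 26, so the inverse digit
    shift is -(shift mod 26) applied mod 10, not -shift mod 10; reusing the
    forward map with the negated *reduced* shift handles both alphabets.
    """
    shift %= 26
    out: list[str] = []
    for ch in ciphertext:
        if "A" <= ch <= "Z":
            out.append(chr((ord(ch) - 65 - shift) % 26 + 65))
        elif "a" <= ch <= "z":
            out.append(chr((ord(ch) - 97 - shift) % 26 + 97))
        elif "0" <= ch <= "9":
            out.append(chr((ord(ch) - 48 - shift) % 10 + 48))
        else:
            out.append(ch)
    return "".join(out)


def _hash_password(password: str, salt: str) -> str:
    return hashlib.sha256((salt + password).encode("utf-8")).hexdigest()


class CredentialStore:
    """In-memory credential registry with a tab-separated text on-disk form."""

    def __init__(self) -> None:
        self._records: dict[str, CredentialRecord] = {}

    def __contains__(self, username: str) -> bool:
        return username in self._records

    def __len__(self) -> int:
        return len(self._records)

    def get(self, username: str) -> CredentialRecord | None:
        return self._records.get(username)

    def register(
        self,
        details: PatientDetails,
        shift: int = DEFAULT_SHIFT,
        *,
        salt: str | None = None,
    ) -> CredentialRecord:
        """Register a patient, computing their cipher token.

        ``salt`` may be pinned for reproducible stores; by default a fresh
        random salt is drawn.
        """
        if details.username in self._records:
            raise RegistrationError(
                f"username {details.username!r} already registered"
            )
        combined = combine_ids(details.patient_id, details.hospital_id)
        token = substitution_encrypt(combined, shift)
        salt = secrets.token_hex(8) if salt is None else salt
        record = CredentialRecord(
            details=details,
            combined_text=combined,
            cipher_token=token,
            shift_key=shift % 26,
            password_salt=salt,
            password_hash=_hash_password(details.password, salt),
        )
        self._records[details.username] = record
        return record

    def verify(
        self, username: str, password: str, presented_token: str
    ) -> AuthDecision:
        """Authorize iff username, password, and cipher token all match."""
        record = self._records.get(username)
        if record is None:
            return AuthDecision("unauthorized", "unknown username")
        if _hash_password(password, record.password_salt) != record.password_hash:
            return AuthDecision("unauthorized", "password mismatch")
        if presented_token != record.cipher_token:
            return AuthDecision("unauthorized", "ciphertext mismatch")
        return AuthDecision("authorized", "all credentials matched")

    # -- text serialization -------------------------------------------------

    _FIELDS = (
        "username patient_name sex age address patient_id hospital_id "
        "doctor_name"
    ).split()

    def to_text(self) -> str:
        lines = []
        for record in self._records.values():
            d = record.details
            cells = [getattr(d, f) for f in self._FIELDS]
            cells += [
                record.combined_text,
                record.cipher_token,
                str(record.shift_key),
                record.password_salt,
                record.password_hash,
            ]
            for cell in cells:
                if "\t" in cell or "\n" in cell:
                    raise ValidationError(
                        "credential fields may not contain tabs or newlines"
                    )
            lines.append("\t".join(cells))
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_text(cls, text: str) -> "CredentialStore":
        store = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != len(cls._FIELDS) + 5:
                raise ValidationError("malformed credential record")
            named = dict(zip(cls._FIELDS, cells))
            details = PatientDetails(password="", **named)
            record = CredentialRecord(
                details=details,
                combined_text=cells[-5],
                cipher_token=cells[-4],
                shift_key=int(cells[-3]),
                password_salt=cells[-2],
                password_hash=cells[-1],
            )
            store._records[details.username] = record
        return store

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CredentialStore":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))


def register_patient(
    store: CredentialStore, details: PatientDetails, shift: int = DEFAULT_SHIFT
) -> CredentialRecord:
    """Module-level convenience wrapper over :meth:`CredentialStore.register`."""
    return store.register(details, shift)


def verify_login(
    store: CredentialStore, username: str, password: str, presented_token: str
) -> AuthDecision:
    """Module-level convenience wrapper over :meth:`CredentialStore.verify`."""
    return store.verify(username, password, presented_token)
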