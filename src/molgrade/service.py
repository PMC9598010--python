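"""JSON-over-HTTP grading endpoint with JWT authentication.

The correction service is deliberately stateless: it parses the structures
in a request, grades, answers, and remembers nothing. The WSGI application
returned by :func:`create_app` can be mounted under any WSGI server;
:func:`serve` runs it on the stdlib reference server, which is all a
single-institution deployment needs.

Authentication uses compact JWTs (``header.payload.signature``, each part
Base64Url) signed with HMAC-SHA256 over a secret shared with the LMS. The
payload must carry an ``iat`` (issued-at) claim inside a configurable
freshness window; tokens signed with any other algorithm — including
``none`` — are rejected outright. Failed authentications are logged with
the caller's IP so an administrator can be notified.

Routes:

* ``GET /v1/health`` — liveness probe, no auth.
* ``POST /v1/grade`` — body is a :class:`GradingRequest` JSON object,
  ``Authorization: Bearer <JWT>`` required. Responses mirror
  :class:`molgrade.grader.GradeResult` exactly, at full precision.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import logging
import time
from dataclasses import dataclass
from typing import Callable, Iterable

from pydantic import BaseModel, Field, ValidationError

from .errors import (
    AuthenticationError,
    ConfigurationError,
    MolGradeError,
    StructureRejectedError,
)
from .fragmenter import FragmentationScheme
from .grader import GradingParams, grade_answer
from .similarity import DEFAULT_VARIANT
from .structures import Molecule, read_editor_json, read_molfile

__all__ = [
    "AuthToken",
    "GradingRequest",
    "issue_token",
    "verify_token",
    "handle_grade",
    "create_app",
    "serve",
]

log = logging.getLogger("molgrade.service")

_ALLOWED_ALGS = ("HS256",)
_CLOCK_SKEW = 30.0  # seconds of tolerated clock drift for future iat


def _b64url_encode(data: bytes) -> str:
    return base64.urlsafe_b64encode(data).rstrip(b"=").decode("ascii")


def _b64url_decode(data: str) -> bytes:
    pad = "=" * (-len(data) % 4)
    return base64.urlsafe_b64decode(data + pad)


@dataclass
class AuthToken:
    """A verified JWT: decoded header, payload, and raw signature bytes."""

    header: dict
    payload: dict
    signature: bytes


def issue_token(
    secret: bytes | str,
    issuer: str = "moodle",
    iat: float | None = None,
    extra: dict | None = None,
) -> str:
    """Create a compact HS256 JWT (used by clients, tests and examples)."""
    if isinstance(secret, str):
        secret = secret.encode()
    header = {"alg": "HS256", "typ": "JWT"}
    payload = {"iss": issuer, "iat": time.time() if iat is None else iat}
    if extra:
        payload.update(extra)
    signing_input = (
        _b64url_encode(json.dumps(header, separators=(",", ":")).encode())
        + "."
        + _b64url_encode(json.dumps(payload, separators=(",", ":")).encode())
    )
    sig = hmac.new(secret, signing_input.encode("ascii"), hashlib.sha256).digest()
    return signing_input + "." + _b64url_encode(sig)


def verify_token(
    token: str,
    secret: bytes | str,
    max_age: float = 300.0,
    now: float | None = None,
) -> AuthToken:
    """Verify signature and freshness; raises AuthenticationError otherwise.

    The signature comparison is constant-time. ``max_age`` bounds
    ``now − iat``; a small clock skew is tolerated for tokens from the
    near future.
    """
    if isinstance(secret, str):
        secret = secret.encode()
    parts = token.split(".")
    if len(parts) != 3:
        raise AuthenticationError("malformed token: expected three segments")
    signing_input = parts[0] + "." + parts[1]
    try:
        header = json.loads(_b64url_decode(parts[0]))
        payload = json.loads(_b64url_decode(parts[1]))
        signature = _b64url_decode(parts[2])
    except (ValueError, json.JSONDecodeError):
        raise AuthenticationError("malformed token: undecodable segment") from None
    if not isinstance(header, dict) or header.get("alg") not in _ALLOWED_ALGS:
        raise AuthenticationError(
            f"unsupported signature algorithm {header.get('alg') if isinstance(header, dict) else None!r}"
        )
    expected = hmac.new(secret, signing_input.encode("ascii"), hashlib.sha256).digest()
    if not hmac.compare_digest(signature, expected):
        raise AuthenticationError("signature verification failed")
    iat = payload.get("iat") if isinstance(payload, dict) else None
    if not isinstance(iat, (int, float)):
        raise AuthenticationError("missing or invalid iat claim")
    now = time.time() if now is None else now
    if now - iat > max_age:
        raise AuthenticationError("token expired")
    if iat - now > _CLOCK_SKEW:
        raise AuthenticationError("token issued in the future")
    return AuthToken(header=header, payload=payload, signature=signature)


# ---------------------------------------------------------------------------
# Request handling
# ---------------------------------------------------------------------------

class GradingRequest(BaseModel):
    """Schema of the ``POST /v1/grade`` body.

    Structures are either MOL V2000 text or editor-JSON objects (strings
    starting with ``{`` are parsed as editor JSON).
    """

    student_structure: str | dict
    teacher_structures: list[str | dict] = Field(min_length=1)
    alpha: float = Field(default=1.0, gt=0)
    threshold: float = Field(default=0.0, ge=0.0, le=1.0)
    stereo: bool = False
    variant: str = DEFAULT_VARIANT
    request_id: str = ""


def _parse_structure(obj: str | dict) -> Molecule:
    if isinstance(obj, dict):
        return read_editor_json(obj)
    if obj.lstrip().startswith("{"):
        return read_editor_json(obj)
    return read_molfile(obj)


def handle_grade(
    request: GradingRequest, scheme: FragmentationScheme | None = None
) -> dict:
    """Grade an authenticated request; returns the response body as a dict."""
    try:
        student = _parse_structure(request.student_structure)
    except MolGradeError as exc:
        raise StructureRejectedError(str(exc), side="student") from exc
    teachers = []
    for k, t in enumerate(request.teacher_structures):
        try:
            teachers.append(_parse_structure(t))
        except MolGradeError as exc:
            raise StructureRejectedError(str(exc), side=f"teacher[{k}]") from exc
    params = GradingParams(
        alpha=request.alpha,
        threshold=request.threshold,
        stereo_required=request.stereo,
        scheme=scheme or FragmentationScheme(),
        variant=request.variant,  # type: ignore[arg-type]
    )
    result = grade_answer(student, teachers, params)
    body = result.to_dict()
    body.pop("similarity")
    body["request_id"] = request.request_id
    return body


# ---------------------------------------------------------------------------
# WSGI application
# ---------------------------------------------------------------------------

def create_app(
    secret: bytes | str,
    scheme: FragmentationScheme | None = None,
    max_age: float = 300.0,
) -> Callable:
    """Build the WSGI application for the grading service."""

    def app(environ: dict, start_response: Callable) -> Iterable[bytes]:
        method = environ.get("REQUEST_METHOD", "GET")
        path = environ.get("PATH_INFO", "/")

        def respond(status: str, body: dict) -> Iterable[bytes]:
            payload = json.dumps(body).encode()
            start_response(
                status,
                [
                    ("Content-Type", "application/json"),
                    ("Content-Length", str(len(payload))),
                ],
            )
            return [payload]

        if method == "GET" and path == "/v1/health":
            return respond("200 OK", {"status": "ok"})
        if not (method == "POST" and path == "/v1/grade"):
            return respond("404 Not Found", {"error": "unknown route"})

        remote = environ.get("REMOTE_ADDR", "unknown")
        auth = environ.get("HTTP_AUTHORIZATION", "")
        if not auth.startswith("Bearer "):
            log.warning("unauthenticated request from %s: missing bearer token", remote)
            return respond("401 Unauthorized", {"error": "missing bearer token"})
        try:
            verify_token(auth[len("Bearer "):], secret, max_age=max_age)
        except AuthenticationError as exc:
            log.warning("authentication failure from %s: %s", remote, exc)
            return respond("401 Unauthorized", {"error": str(exc)})

        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
            raw = environ["wsgi.input"].read(length) if length else b"{}"
            request = GradingRequest.model_validate_json(raw)
        except ValidationError as exc:
            first = exc.errors()[0]
            field = ".".join(str(p) for p in first["loc"]) or "body"
            return respond(
                "422 Unprocessable Entity",
                {"error": f"invalid request field {field}: {first['msg']}"},
            )
        except (ValueError, KeyError) as exc:
            return respond("422 Unprocessable Entity", {"error": f"bad JSON body: {exc}"})

        try:
            body = handle_grade(request, scheme=scheme)
        except (StructureRejectedError, ConfigurationError) as exc:
            return respond("422 Unprocessable Entity", {"error": str(exc)})
        except MolGradeError as exc:
            return respond("422 Unprocessable Entity", {"error": str(exc)})
        except Exception:  # pragma: no cover - defensive
            log.exception("internal error while grading")
            return respond("500 Internal Server Error", {"error": "internal error"})
        return respond("200 OK", body)

    return app


def serve(
    host: str = "127.0.0.1",
    port: int = 8080,
    secret: bytes | str = b"",
    scheme: FragmentationScheme | None = None,
) -> None:  # pragma: no cover - thin wrapper around wsgiref
    """Run the grading service on the stdlib WSGI reference server."""
    from wsgiref.simple_server import make_server

    if not secret:
        raise ConfigurationError("a shared secret is required to serve")
    with make_server(host, port, create_app(secret, scheme)) as httpd:
        log.info("grading service listening on %s:%d", host, port)
        httpd.serve_forever()
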