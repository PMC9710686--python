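"""REST grounding service.

A small WSGI application (Python standard library only) exposing:

* ``POST /ground`` — body ``{"text": ..., "context"?: ...,
  "organisms"?: [...]}``; responds with the JSON list of scored
  matches, byte-identical to the CLI's output for the same inputs.
* ``GET /models`` — the entity strings with deployed disambiguation
  models.

Errors come back as JSON payloads with an ``error`` key: HTTP 400 for
missing/invalid input, 413 for oversized request bodies.
"""

from __future__ import annotations

import json
import logging
from typing import Callable, Iterable

from .stringmatch import Grounder, scored_match_to_dict

logger = logging.getLogger(__name__)

__all__ = ["create_app", "serve", "render_matches", "MAX_BODY_BYTES"]

#: request bodies above this size are rejected with 413
MAX_BODY_BYTES = 1_000_000


def render_matches(matches) -> bytes:
    """Canonical JSON rendering of a match list, shared by CLI and REST."""
    return (
        json.dumps(
            [scored_match_to_dict(m) for m in matches],
            ensure_ascii=False,
            indent=1,
            sort_keys=True,
        )
        + "\n"
    ).encode("utf-8")


def _json_response(start_response, status: str, payload: bytes) -> list[bytes]:
    start_response(
        status,
        [
            ("Content-Type", "application/json; charset=utf-8"),
            ("Content-Length", str(len(payload))),
        ],
    )
    return [payload]


def _error(start_response, status: str, message: str) -> list[bytes]:
    body = (json.dumps({"error": message}) + "\n").encode("utf-8")
    return _json_response(start_response, status, body)


def create_app(grounder: Grounder) -> Callable:
    """Build the WSGI application around a grounder."""

    def app(environ, start_response) -> Iterable[bytes]:
        method = environ.get("REQUEST_METHOD", "GET")
        path = environ.get("PATH_INFO", "/")

        if path == "/ground" and method == "POST":
            try:
                length = int(environ.get("CONTENT_LENGTH") or 0)
            except ValueError:
                length = 0
            if length > MAX_BODY_BYTES:
                return _error(
                    start_response,
                    "413 Payload Too Large",
                    f"request body exceeds {MAX_BODY_BYTES} bytes",
                )
            raw = environ["wsgi.input"].read(length) if length else b""
            try:
                payload = json.loads(raw.decode("utf-8")) if raw else {}
            except (UnicodeDecodeError, json.JSONDecodeError):
                return _error(start_response, "400 Bad Request", "invalid JSON body")
            if not isinstance(payload, dict) or not payload.get("text"):
                return _error(
                    start_response, "400 Bad Request", "missing required field: text"
                )
            try:
                matches = grounder.ground(
                    payload["text"],
                    context=payload.get("context"),
                    organisms=payload.get("organisms"),
                )
            except ValueError as err:
                return _error(start_response, "400 Bad Request", str(err))
            return _json_response(start_response, "200 OK", render_matches(matches))

        if path == "/models" and method == "GET":
            texts = (
                grounder.models.entity_texts() if grounder.models is not None else []
            )
            body = (json.dumps(texts, ensure_ascii=False) + "\n").encode("utf-8")
            return _json_response(start_response, "200 OK", body)

        return _error(start_response, "404 Not Found", f"no route for {method} {path}")

    return app


def serve(grounder: Grounder, host: str = "127.0.0.1", port: int = 8001) -> None:
    """Run the service with wsgiref's reference server (blocking)."""
    from wsgiref.simple_server import make_server

    app = create_app(grounder)
    with make_server(host, port, app) as httpd:
        logger.info("grounding service listening on http://%s:%d", host, port)
        httpd.serve_forever()
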