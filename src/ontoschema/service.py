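"""HTTP validation service (stdlib, no web framework required).

One endpoint does the work: ``POST /validate`` accepts either an inline
schema or a ``schema_id`` resolving against the server's schema registry,
plus one document or a batch (a JSON array under ``data``).  Validity is
payload, not HTTP status: a well-formed request always gets 200 with the
report(s); 400 covers malformed requests and 404 an unknown ``schema_id``.
``GET /health`` reports liveness.

Report JSON is produced by the same canonical serializer the CLI uses, so
the three interfaces emit byte-identical reports for the same inputs.
"""

from __future__ import annotations

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any, Mapping

from .backend import LocalBackend, OntologyBackend
from .engine import (
    CompileError,
    SchemaRegistry,
    canonical_json,
    compile_schema,
)


class ValidationService:
    """Request handling, independent of the HTTP transport."""

    def __init__(
        self,
        backend: OntologyBackend | None = None,
        registry: SchemaRegistry | None = None,
    ):
        self.backend = backend if backend is not None else LocalBackend()
        self.registry = registry if registry is not None else SchemaRegistry()

    def handle_validate(self, payload: Any) -> tuple[int, str]:
        """Process one /validate request body; return (status, body)."""
        if not isinstance(payload, Mapping):
            return 400, _error("request body must be a JSON object")
        has_schema = "schema" in payload
        has_schema_id = "schema_id" in payload
        if has_schema == has_schema_id:
            return 400, _error(
                "exactly one of 'schema' and 'schema_id' is required"
            )
        if "data" not in payload:
            return 400, _error("'data' is required")

        if has_schema_id:
            schema = self.registry.get(payload["schema_id"])
            if schema is None:
                return 404, _error(
                    f"unknown schema_id {payload['schema_id']!r}"
                )
        else:
            schema = payload["schema"]

        try:
            validator = compile_schema(
                schema, backend=self.backend, registry=self.registry
            )
        except CompileError as exc:
            return 400, _error(str(exc))

        data = payload["data"]
        if isinstance(data, list):
            if not data:
                return 400, _error("batch 'data' must be non-empty")
            reports = validator.validate_many(data)
            return 200, canonical_json([r.to_dict() for r in reports])
        report = validator.validate(data)
        return 200, report.to_json()

    def handle_health(self) -> tuple[int, str]:
        return 200, canonical_json({"status": "ok"})


def _error(message: str) -> str:
    return canonical_json({"error": message})


def _make_handler(service: ValidationService):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args):  # quiet by default
            pass

        def _reply(self, status: int, body: str) -> None:
            raw = body.encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(raw)))
            self.end_headers()
            self.wfile.write(raw)

        def do_GET(self):
            if self.path == "/health":
                self._reply(*service.handle_health())
            else:
                self._reply(404, _error(f"no such path {self.path!r}"))

        def do_POST(self):
            if self.path != "/validate":
                self._reply(404, _error(f"no such path {self.path!r}"))
                return
            length = int(self.headers.get("Content-Length", 0))
            raw = self.rfile.read(length)
            try:
                payload = json.loads(raw)
            except json.JSONDecodeError as exc:
                self._reply(400, _error(f"request body is not JSON: {exc}"))
                return
            self._reply(*service.handle_validate(payload))

    return Handler


def make_server(
    service: ValidationService, host: str = "127.0.0.1", port: int = 0
) -> ThreadingHTTPServer:
    """Bind (port 0 picks a free one) but do not start serving."""
    return ThreadingHTTPServer((host, port), _make_handler(service))


def start_server(
    service: ValidationService, host: str = "127.0.0.1", port: int = 0
) -> tuple[ThreadingHTTPServer, threading.Thread]:
    """Start a daemon-thread server; caller shuts it down."""
    server = make_server(service, host, port)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return server, thread


def serve_forever(
    service: ValidationService, host: str = "0.0.0.0", port: int = 8080
) -> None:
    make_server(service, host, port).serve_forever()
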