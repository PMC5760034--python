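"""HTTP transport for the sync protocol (local trusted network).

Endpoints, all JSON except the snapshot:

- ``POST /sync/entry``    one entry ``{entity_id, entity_type, attribute,
  tag, payload}`` → ack ``{entity_id, attribute, assigned_version}``
- ``POST /sync/diff``     ``{versions: [[entity_id, attribute, version]]}``
  → ``{entries: [[entity_id, entity_type, attribute, tag, payload,
  version]]}``
- ``GET /sync/snapshot``  raw database file bytes
- ``GET /sync/ping``      ``{"ok": true}``

The hub serializes entry updates with a lock, so interleaved clients are
applied in arrival order — exactly the last-device-wins rule.  There is
no authentication: like the original deployment, the hub lives on its
own isolated field network.
"""

from __future__ import annotations

import json
import threading
import urllib.error
import urllib.request
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .errors import MalformedMessageError, TransportError
from .store import EavStore
from .sync import Ack, Transport, server_diff, server_receive_entry


class HubServer:
    """A running hub: wraps ThreadingHTTPServer around a store."""

    def __init__(self, hub: EavStore, host: str = "127.0.0.1", port: int = 0):
        self.hub = hub
        self.lock = threading.Lock()
        handler = _make_handler(hub, self.lock)
        self._httpd = ThreadingHTTPServer((host, port), handler)
        self.host, self.port = self._httpd.server_address[:2]
        self._thread: threading.Thread | None = None

    @property
    def url(self) -> str:
        return f"http://{self.host}:{self.port}"

    def start(self) -> "HubServer":
        self._thread = threading.Thread(
            target=self._httpd.serve_forever, daemon=True)
        self._thread.start()
        return self

    def serve_forever(self) -> None:
        self._httpd.serve_forever()

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread:
            self._thread.join(timeout=5)


def serve(hub: EavStore, host: str = "127.0.0.1",
          port: int = 0) -> HubServer:
    """Start a hub server in a background thread and return it."""
    return HubServer(hub, host, port).start()


def _make_handler(hub: EavStore, lock: threading.Lock):
    class Handler(BaseHTTPRequestHandler):
        protocol_version = "HTTP/1.1"

        def log_message(self, *args):  # quiet by default
            pass

        def _json(self, code: int, obj) -> None:
            body = json.dumps(obj).encode()
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def _read_body(self):
            length = int(self.headers.get("Content-Length", 0))
            return json.loads(self.rfile.read(length) or b"{}")

        def do_GET(self):
            if self.path == "/sync/ping":
                self._json(200, {"ok": True})
            elif self.path == "/sync/snapshot":
                with lock:
                    data = hub.snapshot_bytes()
                self.send_response(200)
                self.send_header("Content-Type", "application/octet-stream")
                self.send_header("Content-Length", str(len(data)))
                self.end_headers()
                self.wfile.write(data)
            else:
                self._json(404, {"error": "not found"})

        def do_POST(self):
            try:
                msg = self._read_body()
            except (ValueError, json.JSONDecodeError):
                self._json(400, {"error": "bad json"})
                return
            if self.path == "/sync/entry":
                try:
                    with lock:
                        ack = server_receive_entry(
                            hub, msg.get("entity_id", ""),
                            msg.get("entity_type", ""),
                            msg.get("attribute", ""),
                            msg.get("tag", ""), msg.get("payload", ""))
                except MalformedMessageError as exc:
                    self._json(400, {"error": str(exc)})
                    return
                self._json(200, {"entity_id": ack.entity_id,
                                 "attribute": ack.attribute,
                                 "assigned_version": ack.assigned_version})
            elif self.path == "/sync/diff":
                versions = [tuple(v) for v in msg.get("versions", [])]
                with lock:
                    entries = server_diff(hub, versions)
                self._json(200, {"entries": [list(e) for e in entries]})
            else:
                self._json(404, {"error": "not found"})

    return Handler


class HttpTransport(Transport):
    """Replica-side client for a :class:`HubServer` URL."""

    def __init__(self, hub_url: str, timeout: float = 10.0):
        self.hub_url = hub_url.rstrip("/")
        self.timeout = timeout

    def _post(self, path: str, obj) -> dict:
        req = urllib.request.Request(
            self.hub_url + path, data=json.dumps(obj).encode(),
            headers={"Content-Type": "application/json"}, method="POST")
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return json.loads(resp.read())
        except urllib.error.HTTPError as exc:
            detail = exc.read().decode(errors="replace")
            raise MalformedMessageError(
                f"hub rejected message: {detail}") from exc
        except OSError as exc:
            raise TransportError(f"hub unreachable: {exc}") from exc

    def push_entry(self, entity_id, entity_type, attribute, tag, payload):
        ack = self._post("/sync/entry", {
            "entity_id": entity_id, "entity_type": entity_type,
            "attribute": attribute, "tag": tag, "payload": payload})
        return Ack(ack["entity_id"], ack["attribute"],
                   ack["assigned_version"])

    def diff(self, versions):
        resp = self._post("/sync/diff",
                          {"versions": [list(v) for v in versions]})
        return [tuple(e) for e in resp["entries"]]

    def snapshot(self) -> bytes:
        try:
            with urllib.request.urlopen(
                    self.hub_url + "/sync/snapshot",
                    timeout=self.timeout) as resp:
                return resp.read()
        except OSError as exc:
            raise TransportError(f"snapshot failed: {exc}") from exc

    def ping(self) -> bool:
        try:
            with urllib.request.urlopen(
                    self.hub_url + "/sync/ping", timeout=self.timeout) as r:
                return json.loads(r.read()).get("ok", False)
        except OSError:
            return False
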