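"""Minimal HTTP redirect endpoint over a loaded registry.

One route: a GET whose path is a compact identifier (optionally with a
provider segment) answers 302 Found with the provider's expanded URL in
``Location``. 302 rather than 301 because provider targets are not
persistent — only the resolver URL is — so clients must not cache the
mapping. ``GET /`` returns a plain-text usage page. Responses are
stateless and deterministic: the pure function :func:`handle_request`
does all the work, and the HTTP layer is a thin stdlib wrapper around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import unquote

from .errors import (
    GrammarError,
    NotFoundError,
    PatternError,
)
from .registry import Registry
from .resolver import DEFAULT_RESOLVER_BASES, resolve

__all__ = ["RedirectResponse", "handle_request", "make_server", "serve"]

log = logging.getLogger("compactid.service")

_USAGE = (
    "compactid redirect service\n"
    "\n"
    "GET /<prefix>:<LUI>             redirect to the default provider\n"
    "GET /<provider>/<prefix>:<LUI>  redirect to a specific provider\n"
    "\n"
    "Examples: /pdb:2gc4   /rcsb/pdb:2gc4   /taxon:9606\n"
)


@dataclass
class RedirectResponse:
    """Outcome of one resolution request: status, Location, diagnostic."""

    status: int
    location: str | None
    body: str


def handle_request(
    path: str, reg: Registry, resolver_bases=DEFAULT_RESOLVER_BASES
) -> RedirectResponse:
    """Resolve a URL path to a redirect response.

    Success is 302 with ``Location`` set to the provider target URL.
    Unknown prefixes/providers map to 404; grammar errors and pattern
    failures map to 400. ``/`` yields the usage page.
    """
    decoded = unquote(path)
    if decoded.startswith("/"):
        decoded = decoded[1:]
    if not decoded:
        return RedirectResponse(200, None, _USAGE)
    try:
        res = resolve(reg, decoded, resolver_bases)
    except (GrammarError, PatternError) as exc:
        return RedirectResponse(400, None, f"bad request: {exc}\n")
    except NotFoundError as exc:
        return RedirectResponse(404, None, f"not found: {exc}\n")
    return RedirectResponse(302, res.target_url, f"redirecting to {res.target_url}\n")


def make_server(
    reg: Registry, port: int = 8080, resolver_bases=DEFAULT_RESOLVER_BASES
) -> ThreadingHTTPServer:
    """Build (but do not start) the HTTP server bound to ``port``."""

    class Handler(BaseHTTPRequestHandler):
        def do_GET(self):  # noqa: N802 - stdlib naming
            resp = handle_request(self.path, reg, resolver_bases)
            self.send_response(resp.status)
            if resp.location is not None:
                self.send_header("Location", resp.location)
            body = resp.body.encode("utf-8")
            self.send_header("Content-Type", "text/plain; charset=utf-8")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def log_message(self, fmt, *args):  # one line per request
            log.info(
                "%s %s -> %s", self.address_string(), self.path, fmt % args
            )

    return ThreadingHTTPServer(("", port), Handler)


def serve(reg: Registry, port: int = 8080, resolver_bases=DEFAULT_RESOLVER_BASES) -> None:
    """Run the redirect service until interrupted."""
    httpd = make_server(reg, port, resolver_bases)
    log.info("serving on port %d", httpd.server_address[1])
    try:
        httpd.serve_forever()
    except KeyboardInterrupt:  # pragma: no cover - interactive
        pass
    finally:
        httpd.server_close()
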