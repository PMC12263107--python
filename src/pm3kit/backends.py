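"""Completion-backend contract, deterministic mock, and HTTP adapter.

Downstream of retrieval, a completion backend answers the predefined
queries: "is the query variant reported in this context?" (variant_hit),
"which other variants does the same patient carry?" (in_trans), SQL
generation for the table engine, and free-text summarisation. The
:class:`MockBackend` implements the behavioural contract those answers
must satisfy — short verdicts with a verbatim evidence span — with pure
rule-based logic, so the whole pipeline runs deterministically with no
model weights. :class:`HTTPBackend` adapts the same contract to a local
model server speaking the Ollama generate API.
"""

from __future__ import annotations

import json
import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Protocol

from .variants import RepresentationSet, Tier, compile_patterns

DEFAULT_CONTEXT_BUDGET = 16000  # characters


class BackendUnavailableError(RuntimeError):
    """The completion server cannot be reached."""


@dataclass
class BackendRequest:
    task: str  # variant_hit | in_trans | sql_generation | summarize
    context: str
    variant_forms: Optional[RepresentationSet] = None
    prompt_template_id: Optional[str] = None

    _TASKS = frozenset({"variant_hit", "in_trans", "sql_generation", "summarize"})

    def __post_init__(self) -> None:
        if self.task not in self._TASKS:
            raise ValueError(f"unknown backend task: {self.task!r}")
        if self.prompt_template_id is None:
            self.prompt_template_id = self.task


@dataclass
class BackendAnswer:
    verdict: str  # yes | no | n/a
    extracted_variants: list[str] = field(default_factory=list)
    rationale_span: str = ""
    sql: Optional[str] = None


class Backend(Protocol):
    def complete(self, request: BackendRequest) -> BackendAnswer: ...


def load_template(template_id: str) -> str:
    """Load a versioned prompt template shipped with the package."""
    return (
        resources.files("pm3kit.templates")
        .joinpath(f"{template_id}.txt")
        .read_text(encoding="utf-8")
    )


# Generic variant-mention patterns used by the mock in_trans extractor:
# coding DNA events and protein changes in long or shorthand spelling.
MENTION_PATTERNS: tuple[re.Pattern, ...] = (
    re.compile(
        r"c\.\d+(?:_\d+)?"
        r"(?:[ACGTacgt]>[ACGTacgt]"
        r"|delins[ACGTacgt]+"
        r"|del[ACGTacgt]*"
        r"|dup[ACGTacgt]*"
        r"|ins[ACGTacgt]+)"
    ),
    re.compile(r"p\.\(?[A-Z][a-z]{2}\d+(?:[A-Z][a-z]{2}|Ter|\*|X)\)?"),
    re.compile(r"(?<!\.)\b[A-Z][a-z]{2}\d+(?:[A-Z][a-z]{2}|Ter)\b"),
    re.compile(r"(?<!\w)[ACDEFGHIKLMNPQRSTVWY]\d+[ACDEFGHIKLMNPQRSTVWY](?!\w)|"
               r"(?<!\w)[ACDEFGHIKLMNPQRSTVWY]\d+[*X](?!\w)"),
)


def scan_variant_mentions(text: str) -> list[tuple[int, str]]:
    """All HGVS-like mentions in ``text`` as (offset, mention), in order.

    Mentions fully contained in a longer mention (the bare protein change
    inside its ``p.(...)`` spelling) are suppressed.
    """
    spans: list[tuple[int, int]] = []
    for pat in MENTION_PATTERNS:
        spans.extend(m.span() for m in pat.finditer(text))
    spans.sort(key=lambda s: (s[0], -(s[1] - s[0])))
    kept: list[tuple[int, int]] = []
    for start, end in spans:
        if any(a <= start and end <= b for a, b in kept):
            continue
        kept.append((start, end))
    return [(a, text[a:b]) for a, b in sorted(kept)]


class MockBackend:
    """Deterministic rule-based backend.

    * variant_hit: answers yes iff a full-notation (T0) spelling of the
      query occurs in the context; the matched span is the rationale.
    * in_trans: extracts every HGVS-like mention from the context,
      removes mentions of the query variant itself, and returns the
      remainder deduplicated in order of first occurrence.
    * sql_generation: declines (``sql=None``) so the table engine uses
      its deterministic template query.
    * summarize: echoes the first non-empty context line as evidence.
    """

    def __init__(self, context_budget: int = DEFAULT_CONTEXT_BUDGET):
        self.context_budget = context_budget

    def complete(self, request: BackendRequest) -> BackendAnswer:
        context = request.context[: self.context_budget]
        if request.task == "variant_hit":
            return self._variant_hit(context, request.variant_forms)
        if request.task == "in_trans":
            return self._in_trans(context, request.variant_forms)
        if request.task == "sql_generation":
            return BackendAnswer(verdict="n/a", sql=None)
        first_line = next(
            (ln.strip() for ln in context.splitlines() if ln.strip()), ""
        )
        return BackendAnswer(verdict="n/a", rationale_span=first_line)

    def _variant_hit(
        self, context: str, forms: Optional[RepresentationSet]
    ) -> BackendAnswer:
        if forms is None:
            return BackendAnswer(verdict="n/a")
        m = compile_patterns(forms, Tier.T0_FULL).search(context)
        if m:
            return BackendAnswer(verdict="yes", rationale_span=m.text)
        return BackendAnswer(verdict="no")

    def _in_trans(
        self, context: str, forms: Optional[RepresentationSet]
    ) -> BackendAnswer:
        mentions = scan_variant_mentions(context)
        query_pats = (
            compile_patterns(forms, Tier.T0_FULL) if forms is not None else None
        )
        out: list[str] = []
        rationale = ""
        for _, mention in mentions:
            if query_pats is not None and query_pats.fullmatch(mention):
                continue
            if mention not in out:
                out.append(mention)
                if not rationale:
                    rationale = mention
        return BackendAnswer(
            verdict="yes" if out else "no",
            extracted_variants=out,
            rationale_span=rationale,
        )


class HTTPBackend:
    """Adapter for a local completion server (Ollama generate API).

    Sends the shipped prompt template verbatim with the context and query
    spliced in, requests deterministic decoding, and parses the reply
    into the :class:`BackendAnswer` shape. Requests and responses can be
    logged as JSON lines for audit.
    """

    def __init__(
        self,
        url: str,
        model: str,
        timeout: float = 120.0,
        log_path: Optional[str] = None,
        context_budget: int = DEFAULT_CONTEXT_BUDGET,
    ):
        self.url = url.rstrip("/")
        self.model = model
        self.timeout = timeout
        self.log_path = log_path
        self.context_budget = context_budget

    def complete(self, request: BackendRequest) -> BackendAnswer:
        template = load_template(request.prompt_template_id or request.task)
        forms = request.variant_forms
        prompt = template.format(
            context=request.context[: self.context_budget],
            variant=forms.variant.raw if forms is not None else "",
            representations=", ".join(forms.all_forms()) if forms is not None else "",
        )
        payload = {
            "model": self.model,
            "prompt": prompt,
            "stream": False,
            "options": {"temperature": 0.0, "seed": 0},
        }
        req = urllib.request.Request(
            f"{self.url}/api/generate",
            data=json.dumps(payload).encode("utf-8"),
            headers={"Content-Type": "application/json"},
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, ValueError) as exc:
            raise BackendUnavailableError(
                f"completion server at {self.url} unavailable: {exc}"
            ) from exc
        text = body.get("response", "")
        self._log(request, text)
        return self._parse(request, text)

    def _parse(self, request: BackendRequest, text: str) -> BackendAnswer:
        if request.task == "sql_generation":
            return BackendAnswer(verdict="n/a", sql=text.strip() or None)
        lowered = text.strip().lower()
        if lowered.startswith("yes"):
            verdict = "yes"
        elif lowered.startswith("no"):
            verdict = "no"
        else:
            verdict = "n/a"
        mentions = [m for _, m in scan_variant_mentions(text)]
        span = mentions[0] if mentions and mentions[0] in request.context else ""
        return BackendAnswer(
            verdict=verdict,
            extracted_variants=list(dict.fromkeys(mentions)),
            rationale_span=span,
        )

    def _log(self, request: BackendRequest, response_text: str) -> None:
        if not self.log_path:
            return
        entry = {
            "task": request.task,
            "model": self.model,
            "context_chars": len(request.context),
            "response": response_text,
        }
        with open(self.log_path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def make_backend(spec: str, log_path: Optional[str] = None) -> Backend:
    """Build a backend from a CLI-style spec: ``mock`` or ``http:<url>/<model>``."""
    if spec == "mock":
        return MockBackend()
    if spec.startswith("http:"):
        rest = spec[len("http:"):]
        url, _, model = rest.rpartition("/")
        if not url or not model:
            raise ValueError(f"backend spec needs http:<url>/<model>, got {spec!r}")
        return HTTPBackend(url=url, model=model, log_path=log_path)
    raise ValueError(f"unknown backend spec: {spec!r}")
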