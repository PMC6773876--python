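"""Static single-file HTML summary of an enrichment run."""

from __future__ import annotations

import html

import pandas as pd

__all__ = ["render_report"]

_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Active-subnetwork enrichment report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
th, td {{ border: 1px solid #999; padding: 4px 8px; font-size: 0.9em; }}
th {{ background: #eee; }}
caption {{ text-align: left; font-weight: bold; padding-bottom: 0.5em; }}
</style>
</head>
<body>
<h1>Active-subnetwork-oriented enrichment results</h1>
<h2>Parameters</h2>
<table><caption>Run configuration</caption>
{params}
</table>
<h2>Enriched pathways ({n_rows})</h2>
<table>
{table}
</table>
</body>
</html>
"""


def _params_rows(params: dict) -> str:
    return "\n".join(
        f"<tr><th>{html.escape(str(k))}</th><td>{html.escape(str(v))}</td></tr>"
        for k, v in params.items()
    )


def _table_rows(table: pd.DataFrame) -> str:
    head = "<tr>" + "".join(f"<th>{html.escape(c)}</th>" for c in table.columns) + "</tr>"
    rows = []
    for _, row in table.iterrows():
        cells = []
        for value in row:
            if isinstance(value, (list, tuple, set, frozenset)):
                value = ";".join(sorted(value))
            elif isinstance(value, float):
                value = f"{value:.3g}"
            cells.append(f"<td>{html.escape(str(value))}</td>")
        rows.append("<tr>" + "".join(cells) + "</tr>")
    return "\n".join([head, *rows])


def render_report(result_table: pd.DataFrame, params: dict) -> str:
    """Render the result table and the run parameters as one HTML page."""
    return _PAGE.format(
        params=_params_rows(params),
        table=_table_rows(result_table),
        n_rows=len(result_table),
    )
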