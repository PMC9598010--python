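"""The JSON grading service, end to end in one process.

Starts the WSGI service on a local port, issues an HMAC-SHA256 JWT with the
shared secret, posts a grading request over HTTP and prints the response —
the same exchange an LMS plugin performs against a deployed server.
"""

import http.client
import json
import threading
from wsgiref.simple_server import make_server

from molgrade.fixtures import build_nitrosyl_fluoride
from molgrade.service import create_app, issue_token
from molgrade.structures import write_molfile

SECRET = "shared-between-lms-and-grader"

server = make_server("127.0.0.1", 0, create_app(SECRET))
threading.Thread(target=server.serve_forever, daemon=True).start()
port = server.server_address[1]

body = json.dumps(
    {
        "student_structure": write_molfile(build_nitrosyl_fluoride(False)),
        "teacher_structures": [write_molfile(build_nitrosyl_fluoride(True))],
        "alpha": 1.0,
        "threshold": 0.0,
        "stereo": False,
        "request_id": "demo-1",
    }
)
conn = http.client.HTTPConnection("127.0.0.1", port)
conn.request(
    "POST",
    "/v1/grade",
    body=body,
    headers={
        "Authorization": f"Bearer {issue_token(SECRET)}",
        "Content-Type": "application/json",
    },
)
response = conn.getresponse()
print(response.status, json.loads(response.read()))
server.shutdown()
# 200 {'grade': 0.9021..., 'g_rest': 0.9021..., 'matched_index': 0,
#      'stereo_detail': None, 'request_id': 'demo-1'} — full precision on the
# wire; rounding to 0.90 is left to the presenting side.
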