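"""JWT verification and the WSGI grading endpoint."""

import io
import json
import time

import pytest

from molgrade.errors import AuthenticationError
from molgrade.fixtures import build_nitrosyl_fluoride
from molgrade.grader import GradingParams, grade_answer
from molgrade.service import (
    GradingRequest,
    create_app,
    handle_grade,
    issue_token,
    verify_token,
)
from molgrade.structures import write_molfile

SECRET = "correct horse battery staple"


def call(app, path, method="GET", body=None, token=None, remote="203.0.113.7"):
    raw = json.dumps(body).encode() if body is not None else b""
    environ = {
        "REQUEST_METHOD": method,
        "PATH_INFO": path,
        "REMOTE_ADDR": remote,
        "CONTENT_LENGTH": str(len(raw)),
        "wsgi.input": io.BytesIO(raw),
    }
    if token is not None:
        environ["HTTP_AUTHORIZATION"] = f"Bearer {token}"
    captured = {}

    def start_response(status, headers):
        captured["status"] = int(status.split()[0])

    chunks = app(environ, start_response)
    return captured["status"], json.loads(b"".join(chunks))


@pytest.fixture()
def app():
    return create_app(SECRET)


@pytest.fixture(scope="module")
def nof_request():
    teacher = write_molfile(build_nitrosyl_fluoride(True))
    student = write_molfile(build_nitrosyl_fluoride(False))
    return {
        "student_structure": student,
        "teacher_structures": [teacher],
        "alpha": 1.0,
        "threshold": 0.0,
        "stereo": False,
        "request_id": "q-42",
    }


class TestJwt:
    def test_valid_fresh_token_accepted(self):
        token = issue_token(SECRET)
        auth = verify_token(token, SECRET)
        assert auth.header["alg"] == "HS256"
        assert auth.payload["iss"] == "moodle"

    def test_tampered_payload_rejected(self):
        token = issue_token(SECRET)
        head, payload, sig = token.split(".")
        tampered = payload[:-2] + ("A" if payload[-2] != "A" else "B") + payload[-1]
        with pytest.raises(AuthenticationError):
            verify_token(f"{head}.{tampered}.{sig}", SECRET)

    def test_wrong_secret_rejected(self):
        with pytest.raises(AuthenticationError, match="signature"):
            verify_token(issue_token("other secret"), SECRET)

    def test_stale_token_rejected(self):
        token = issue_token(SECRET, iat=time.time() - 3600)
        with pytest.raises(AuthenticationError, match="expired"):
            verify_token(token, SECRET, max_age=300)

    def test_future_token_rejected(self):
        token = issue_token(SECRET, iat=time.time() + 600)
        with pytest.raises(AuthenticationError, match="future"):
            verify_token(token, SECRET)

    def test_alg_none_rejected(self):
        import base64

        header = base64.urlsafe_b64encode(b'{"alg":"none","typ":"JWT"}').rstrip(b"=")
        payload = base64.urlsafe_b64encode(b'{"iat":1}').rstrip(b"=")
        token = header.decode() + "." + payload.decode() + "."
        with pytest.raises(AuthenticationError, match="algorithm"):
            verify_token(token, SECRET)

    def test_malformed_token_rejected(self):
        with pytest.raises(AuthenticationError, match="segments"):
            verify_token("only.two", SECRET)


class TestGradeEndpoint:
    def test_health_requires_no_auth(self, app):
        status, body = call(app, "/v1/health")
        assert (status, body) == (200, {"status": "ok"})

    def test_unauthenticated_request_gets_401_and_no_grade(self, app, nof_request):
        status, body = call(app, "/v1/grade", "POST", nof_request)
        assert status == 401 and "grade" not in body

    def test_bad_signature_gets_401(self, app, nof_request):
        status, _ = call(
            app, "/v1/grade", "POST", nof_request, token=issue_token("wrong")
        )
        assert status == 401

    def test_grades_nitrosyl_fluoride(self, app, nof_request):
        status, body = call(
            app, "/v1/grade", "POST", nof_request, token=issue_token(SECRET)
        )
        assert status == 200
        assert round(body["grade"], 2) == 0.90
        assert body["request_id"] == "q-42"

    def test_identical_structures_grade_one(self, app):
        mol = write_molfile(build_nitrosyl_fluoride(True))
        status, body = call(
            app,
            "/v1/grade",
            "POST",
            {"student_structure": mol, "teacher_structures": [mol]},
            token=issue_token(SECRET),
        )
        assert status == 200 and body["grade"] == 1.0

    def test_glucose_stereo_request(self, app, glucose):
        request = {
            "student_structure": write_molfile(glucose.student),
            "teacher_structures": [write_molfile(t) for t in glucose.teachers],
            "stereo": True,
        }
        status, body = call(app, "/v1/grade", "POST", request, token=issue_token(SECRET))
        assert status == 200
        assert body["g_rest"] == 0.75
        assert body["stereo_detail"] == {
            "correct": 3,
            "total": 4,
            "skeletons_identical": True,
        }

    def test_zero_teacher_structures_is_422(self, app):
        status, body = call(
            app,
            "/v1/grade",
            "POST",
            {"student_structure": "x", "teacher_structures": []},
            token=issue_token(SECRET),
        )
        assert status == 422 and "teacher_structures" in body["error"]

    def test_malformed_structure_names_the_side(self, app, nof_request):
        bad = dict(nof_request, teacher_structures=["garbage"])
        status, body = call(app, "/v1/grade", "POST", bad, token=issue_token(SECRET))
        assert status == 422 and "teacher[0]" in body["error"]

    def test_stateless_identical_requests_identical_responses(self, app, nof_request):
        token = issue_token(SECRET)
        r1 = call(app, "/v1/grade", "POST", nof_request, token=token)
        r2 = call(app, "/v1/grade", "POST", nof_request, token=token)
        assert r1 == r2

    def test_response_matches_library_bit_for_bit(self, nof_request):
        body = handle_grade(GradingRequest(**nof_request))
        result = grade_answer(
            build_nitrosyl_fluoride(False),
            [build_nitrosyl_fluoride(True)],
            GradingParams(),
        )
        assert body["grade"] == result.grade
        assert body["g_rest"] == result.g_rest
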