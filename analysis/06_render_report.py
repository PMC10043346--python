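"""Render the consolidated markdown report for the pipeline run."""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from taclss.report import write_report  # noqa: E402


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--run", default="results/validation")
    args = parser.parse_args()
    path = write_report(args.run)
    print(f"report -> {path}")
    print(open(path).read())


if __name__ == "__main__":
    main()
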