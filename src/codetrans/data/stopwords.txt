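a
an
and
are
as
at
be
by
for
from
in
into
is
of
on
or
per
s
status
than
that
the
to
via
was
were
with
without
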