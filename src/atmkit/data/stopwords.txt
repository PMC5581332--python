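# Default English stop list (one term per line; '#' lines ignored).
# Terms shorter than three characters are removed by the length filter
# regardless, so only length >= 3 entries matter here.
about
above
after
again
all
also
among
and
any
are
been
before
being
below
between
both
but
can
cannot
could
did
does
doing
down
during
each
few
for
from
further
had
has
have
having
her
here
hers
him
his
how
however
into
its
itself
may
might
more
most
must
nor
not
off
once
only
other
our
ours
out
over
own
same
she
should
some
such
than
that
the
their
theirs
them
then
there
these
they
this
those
through
under
until
upon
very
was
were
what
when
where
which
while
who
whom
why
will
with
within
without
would
you
your
yours
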