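a
about
above
across
after
afterwards
again
against
all
almost
alone
along
already
also
although
always
am
among
amongst
an
and
another
any
anybody
anyhow
anyone
anything
anyway
anywhere
are
around
as
at
be
became
because
become
becomes
becoming
been
before
beforehand
behind
being
below
beside
besides
between
beyond
both
but
by
can
cannot
could
did
do
does
doing
done
down
during
each
either
else
elsewhere
enough
especially
even
ever
every
everybody
everyone
everything
everywhere
except
few
first
for
former
formerly
from
further
furthermore
had
has
have
having
he
hence
her
here
hereafter
hereby
herein
hereupon
hers
herself
him
himself
his
how
however
i
if
in
indeed
instead
into
is
it
its
itself
just
last
latter
latterly
least
less
lest
like
likely
little
many
may
maybe
me
meanwhile
might
mine
more
moreover
most
mostly
much
must
my
myself
namely
near
neither
never
nevertheless
next
no
nobody
none
nonetheless
nor
not
nothing
now
nowhere
of
off
often
on
once
one
only
onto
or
other
others
otherwise
our
ours
ourselves
out
over
own
per
perhaps
please
quite
rather
really
regarding
same
second
several
shall
she
should
since
so
some
somebody
somehow
someone
something
sometime
sometimes
somewhat
somewhere
still
such
than
that
the
their
theirs
them
themselves
then
thence
there
thereafter
thereby
therefore
therein
thereupon
these
they
third
this
those
though
through
throughout
thru
thus
to
together
too
toward
towards
under
unless
until
unto
up
upon
us
used
using
usually
various
very
via
was
we
well
were
what
whatever
when
whence
whenever
where
whereafter
whereas
whereby
wherein
whereupon
wherever
whether
which
while
whither
who
whoever
whole
whom
whose
why
will
with
within
without
would
yet
you
your
yours
yourself
yourselves
ought
dare
need
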