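 *******************************************************************************
 **                                                                           **
 **   SYNTHETIC single-point output fixture in the external program's         **
 **   dialect, written by hand for parser tests. Not produced by any real     **
 **   quantum-chemistry run.                                                  **
 **                                                                           **
 *******************************************************************************

 PM7 1SCF MOZYME CHARGE=1 EPS=78.4
 quasidock single point



          GEOMETRY OPTIMISED USING EIGENVECTOR FOLLOWING (EF).
          SCF FIELD WAS ACHIEVED

          FINAL HEAT OF FORMATION =       -987.65432 KCAL/MOL =   -4132.34567 KJ/MOL

          COSMO AREA              =        523.17 SQUARE ANGSTROMS
          COSMO VOLUME            =        712.44 CUBIC ANGSTROMS

          SCF CALCULATIONS        =            1

          FINAL HEAT OF FORMATION =      -1234.56789 KCAL/MOL =   -5165.43210 KJ/MOL

          TOTAL JOB TIME:             1.23 SECONDS

 == MOPAC DONE ==
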